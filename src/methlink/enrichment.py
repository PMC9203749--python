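"""Overlap step: exact binomial enrichment tests and the stepwise cascade.

The cascade intersects the discovery (imputation-based) significant CpG
set with each tissue differential-methylation set in turn, testing at
every iteration whether the overlap exceeds what the analysis-specific
DM rate over the shared CpG universe predicts, with a one-sided
(greater) exact binomial test.  The cascade proceeds only while
p < alpha; the surviving overlap is the enriched (cancer-associated)
CpG set.  Directional variants restrict each analysis to nominally
significant CpGs (uncorrected p < 0.05) of one methylation direction
first.  Annotation-category enrichment uses the two-sided
point-probability-summation binomial convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    k: int               # overlap / hit count
    n: int               # trials
    p0: float            # null proportion
    side: str            # greater | less | two-sided
    p_value: float
    enriched: bool       # p < alpha at construction time
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")


def binom_test(k: int, n: int, p0: float, side: str = "greater") -> float:
    """Exact binomial tail probability.

    ``side='two-sided'`` sums P(X = j) over all j with
    P(X = j) <= (1 + 1e-7) * P(X = k) (point-probability-summation
    convention, as implemented by scipy).
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    alternative = {"greater": "greater", "less": "less",
                   "two-sided": "two-sided"}[side]
    return float(stats.binomtest(int(k), int(n), p0,
                                 alternative=alternative).pvalue)


def _significant_sets(tables: list[pd.DataFrame], fdr: float):
    universe = None
    for t in tables:
        ids = set(t["unit_id"])
        universe = ids if universe is None else (universe & ids)
    if not universe:
        raise ValueError("empty shared CpG universe across analyses")
    sets = []
    for t in tables:
        sig = set(t.loc[(t["fdr"].notna()) & (t["fdr"] < fdr), "unit_id"])
        sets.append(sig & universe)
    return universe, sets


def stepwise_enrichment(primary: pd.DataFrame, others: list[pd.DataFrame],
                        fdr: float = 0.05, alpha: float = 0.05,
                        selections: list[set] | None = None):
    """Iterative overlap cascade.

    ``primary`` is the discovery association table; ``others`` the
    ordered tissue DM tables (one entry runs a single iteration).  When
    ``selections`` is given it supplies the per-table selected CpG sets
    directly (used by the directional analysis) instead of fdr < 0.05.

    Iteration j: current set intersect DM set j; one-sided (greater)
    binomial with n = |current set|, p0 = |DM set j| / |universe|.
    Proceeds only while p < alpha (strict).  Returns
    ``(enriched_set, trace)`` where the trace records each iteration's
    :class:`EnrichmentResult`; the enriched set is empty when any
    iteration fails.
    """
    tables = [primary] + list(others)
    if selections is None:
        universe, sets = _significant_sets(tables, fdr)
    else:
        universe = None
        for t in tables:
            ids = set(t["unit_id"])
            universe = ids if universe is None else (universe & ids)
        if not universe:
            raise ValueError("empty shared CpG universe across analyses")
        sets = [s & universe for s in selections]

    current = sets[0]
    trace = []
    for j, other in enumerate(sets[1:], start=1):
        n = len(current)
        k = len(current & other)
        p0 = len(other) / len(universe)
        if n == 0 or not (0 < p0 < 1):
            p = 1.0
        else:
            p = binom_test(k, n, p0, side="greater")
        res = EnrichmentResult(k=k, n=n, p0=p0 if 0 < p0 < 1 else np.nan,
                               side="greater", p_value=p,
                               enriched=p < alpha, label=f"iteration_{j}")
        trace.append(res)
        if not res.enriched:
            return set(), trace
        current = current & other
    return current, trace


def directional_enrichment(primary: pd.DataFrame,
                           others: list[pd.DataFrame], direction: str,
                           alpha: float = 0.05, nominal_p: float = 0.05):
    """Cascade over nominally significant CpGs of one direction.

    Sign convention: z < 0 is hypomethylated in cases.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    tables = [primary] + list(others)
    sels = []
    for t in tables:
        sign_ok = (t["z"] < 0) if direction == "hypo" else (t["z"] > 0)
        sels.append(set(t.loc[(t["p"] < nominal_p) & sign_ok, "unit_id"]))
    return stepwise_enrichment(primary, others, alpha=alpha,
                               selections=sels)


def annotation_enrichment(cpg_set, category_of: dict, background,
                          unions: dict | None = None,
                          side: str = "two-sided",
                          alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-category exact binomial tests of a CpG set against its
    tested-CpG background.

    ``unions`` maps a label to a list of categories tested jointly
    (e.g. the combined 5'-UTR + intronic + 3'-UTR class).  Enrichment
    vs depletion is read from the sign of k/n - p0; categories absent
    from the background are skipped.
    """
    cpg_set = set(cpg_set)
    background = list(background)
    missing = [c for c in cpg_set | set(background) if c not in category_of]
    if missing:
        raise ValueError(f"uncategorised CpGs: {missing[:5]}")
    cats = {}
    for label in sorted({category_of[c] for c in background}):
        cats[label] = [label]
    if unions:
        cats.update(unions)

    n = len(cpg_set)
    results = []
    for label, members in cats.items():
        members = set(members)
        bg_hits = sum(category_of[c] in members for c in background)
        if bg_hits == 0:
            continue  # category absent from background
        p0 = bg_hits / len(background)
        k = sum(category_of[c] in members for c in cpg_set)
        if p0 >= 1:
            continue
        p = binom_test(k, n, p0, side=side)
        results.append(EnrichmentResult(k=k, n=n, p0=p0, side=side,
                                        p_value=p, enriched=p < alpha,
                                        label=label))
    return results
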