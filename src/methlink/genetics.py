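"""SNP-level characterisation of the meQTLs behind enriched CpGs.

Familial-relative-risk apportionment, LD r2 utilities, GWAS-region
classification, the iterative approximate conditional scan (COJO-style,
reconstructed from marginal summaries and reference LD), fixed-effect
inverse-variance meta-analysis with Cochran's Q, the pleiotropy LD-link
rule and LD-block assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GwasTable, ReferencePanel

logger = logging.getLogger("methlink")

GWS_P = 5e-8        # genome-wide significance
SUGGESTIVE_P = 1e-5


# ---------------------------------------------------------------------------
# familial relative risk
# ---------------------------------------------------------------------------

@dataclass
class FrrConfig:
    """Overall familial relative risk lambda (2 for BrCa, 2.5 for PrCa)."""

    lam: float

    def __post_init__(self):
        if self.lam <= 1:
            raise ValueError("lambda must exceed 1")


def frr_contribution(snps: pd.DataFrame, cfg: FrrConfig,
                     factor2: bool = False) -> float:
    """Proportion of log familial relative risk explained by a SNP set:

        sum_i p_i (1 - p_i) (beta_i^2 - tau_i^2) / ln(lambda)

    with p_i the minor allele frequency, beta_i the log-odds effect and
    tau_i its standard error.  Negative per-SNP terms are retained.  The
    sum is implemented exactly as printed; ``factor2`` switches on the
    conventional 2p(1-p) variance form.
    """
    maf = np.minimum(snps["eaf"].to_numpy(float),
                     1 - snps["eaf"].to_numpy(float))
    beta = snps["beta"].to_numpy(float)
    tau = snps["se"].to_numpy(float)
    terms = maf * (1 - maf) * (beta ** 2 - tau ** 2) / np.log(cfg.lam)
    if factor2:
        terms = 2 * terms
    return float(terms.sum())


# ---------------------------------------------------------------------------
# LD utilities
# ---------------------------------------------------------------------------

def ld_r2(panel: ReferencePanel, snp_a: str, snp_b: str) -> float:
    """Squared sample correlation between two dosage columns."""
    cols = panel.columns([snp_a, snp_b])
    sd = cols.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance SNP in r2 computation")
    r = np.corrcoef(cols[:, 0], cols[:, 1])[0, 1]
    return float(r ** 2)


def pleiotropy_link(meqtl_a, meqtl_b, panel: ReferencePanel,
                    r2_thresh: float = 0.4):
    """Two CpGs are LD-linked when they share a meQTL SNP or any cross
    pair of their meQTL SNPs has r2 above the threshold.

    Returns ``(linked, supporting_pairs)`` where the pairs list holds
    ``(snp_a, snp_b, r2)`` for every qualifying combination (shared
    SNPs appear with r2 = 1.0).
    """
    set_a, set_b = set(meqtl_a), set(meqtl_b)
    if not set_a or not set_b:
        return False, []
    pairs = [(s, s, 1.0) for s in sorted(set_a & set_b)]
    in_panel_a = [s for s in sorted(set_a - set_b) if s in panel._index]
    in_panel_b = [s for s in sorted(set_b - set_a) if s in panel._index]
    for a in in_panel_a:
        for b in in_panel_b:
            r2 = ld_r2(panel, a, b)
            if r2 > r2_thresh:
                pairs.append((a, b, r2))
    return len(pairs) > 0, pairs


def ld_block_assign(cpg_positions: pd.DataFrame, blocks: pd.DataFrame):
    """Interval-containment lookup of CpGs into non-overlapping LD
    blocks.  Returns ``(assignment, occupancy)``; CpGs outside every
    block map to 'unassigned' and are excluded from the occupancy
    histogram."""
    assignment = {}
    for _, row in cpg_positions.iterrows():
        hit = blocks[(blocks["chrom"].astype(str) == str(row["chrom"]))
                     & (blocks["start"] <= row["pos"])
                     & (blocks["end"] >= row["pos"])]
        assignment[row["cpg_id"]] = (hit.iloc[0]["block_id"] if len(hit)
                                     else "unassigned")
    occupancy = {}
    for b in assignment.values():
        if b != "unassigned":
            occupancy[b] = occupancy.get(b, 0) + 1
    return assignment, occupancy


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def classify_region(cpg_chrom: str, cpg_pos: int, gwas: GwasTable,
                    flank: int = 1_000_000) -> str:
    """Class of the +/- flank window around a CpG from the minimum GWAS
    p: genome_wide_significant (p <= 5e-8), suggestive
    (5e-8 < p <= 1e-5), else novel."""
    df = gwas.df
    win = df[(df["chrom"].astype(str) == str(cpg_chrom))
             & (df["pos"] >= cpg_pos - flank)
             & (df["pos"] <= cpg_pos + flank)]
    if len(win) == 0:
        logger.warning("classify_region: no SNP within the window, "
                       "classified novel")
        return "novel"
    pmin = win["p"].min()
    if pmin <= GWS_P:
        return "genome_wide_significant"
    if pmin <= SUGGESTIVE_P:
        return "suggestive"
    return "novel"


# ---------------------------------------------------------------------------
# iterative conditional scan
# ---------------------------------------------------------------------------

@dataclass
class ConditionalTrace:
    """Ordered record of an approximate conditional/joint scan."""

    region_id: str
    selected: list = field(default_factory=list)   # snp ids, entry order
    p_gwas: dict = field(default_factory=dict)     # marginal p at entry
    p_cond: dict = field(default_factory=dict)     # conditional p at entry
    r2_to_selected: dict = field(default_factory=dict)
    skipped_collinear: list = field(default_factory=list)
    termination: str = ""


def group_cpgs_by_window(cpg_positions: pd.DataFrame,
                         merge_window: int = 1_000_000) -> list[list[str]]:
    """Pool CpGs lying within ``merge_window`` of each other (single
    linkage along the chromosome) into one conditional-analysis region."""
    regions = []
    for chrom, grp in cpg_positions.groupby("chrom"):
        grp = grp.sort_values("pos")
        current, last_pos = [], None
        for _, row in grp.iterrows():
            if last_pos is not None and row["pos"] - last_pos > merge_window:
                regions.append(current)
                current = []
            current.append(row["cpg_id"])
            last_pos = row["pos"]
        if current:
            regions.append(current)
    return regions


def conditional_scan(snp_ids, gwas: GwasTable, panel: ReferencePanel,
                     p_entry: float = 0.05, r2_cap: float = 0.9,
                     region_id: str = "region") -> ConditionalTrace:
    """COJO-style iterative selection of independent meQTL SNPs from
    marginal summaries plus reference LD.

    The joint normal equations are reconstructed as
    X'X ~ n * diag(sqrt(d)) R diag(sqrt(d)) with d_j = 2 p_j (1 - p_j)
    (GWAS allele frequencies), R the panel correlation, shared
    n = median GWAS n, and X'y_j = n d_j beta_j.  The phenotypic
    variance is inferred from the marginal summaries (median of
    d (n se^2 + beta^2)), the residual variance is re-estimated after
    each selection (floored at 0.1 of the phenotypic variance), and the
    candidate's conditional p is a two-sided normal test of its joint
    coefficient.  Candidates with max r2 above ``r2_cap`` to the
    selected set are never chosen; a singular system skips the
    candidate with a collinearity flag.
    """
    df = gwas.df[gwas.df["snp_id"].isin(set(snp_ids))]
    df = df[df["snp_id"].isin(set(panel.snp_ids))].reset_index(drop=True)
    trace = ConditionalTrace(region_id=region_id)
    if len(df) == 0:
        trace.termination = "no entry"
        return trace

    ids = list(df["snp_id"])
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    p_marg = df["p"].to_numpy(float)
    freq = df["eaf"].to_numpy(float)
    d = 2 * freq * (1 - freq)
    n = float(df["n"].median())
    D = panel.columns(ids)
    R = np.corrcoef(D, rowvar=False)
    if R.ndim == 0:
        R = np.array([[1.0]])
    sq = np.sqrt(d)
    # phenotypic variance inferred from the marginal summaries
    vp = float(np.median(d * (n * se ** 2) + d * beta ** 2))
    xtx_full = n * (sq[:, None] * R * sq[None, :])
    xty = n * d * beta

    m = len(ids)
    selected: list[int] = []

    def joint_p_for(candidate: int):
        idx = selected + [candidate]
        A = xtx_full[np.ix_(idx, idx)]
        b_rhs = xty[idx]
        try:
            coef = np.linalg.solve(A, b_rhs)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(coef)) or np.linalg.cond(A) > 1e10:
            return None
        k = len(idx)
        rss = n * vp - coef @ b_rhs
        sigma2 = max(rss, 0.1 * n * vp) / max(n - k - 1, 1)
        cov = sigma2 * np.linalg.inv(A)
        se_c = np.sqrt(cov[-1, -1])
        z = coef[-1] / se_c
        return float(np.clip(2 * stats.norm.sf(abs(z)),
                             np.finfo(float).tiny, 1.0))

    # first selection: smallest marginal p below threshold
    j0 = int(np.argmin(p_marg))
    if p_marg[j0] >= p_entry:
        trace.termination = "no entry"
        return trace
    selected.append(j0)
    trace.selected.append(ids[j0])
    trace.p_gwas[ids[j0]] = float(p_marg[j0])
    trace.p_cond[ids[j0]] = float(p_marg[j0])
    trace.r2_to_selected[ids[j0]] = 0.0

    while True:
        best = None
        for c in range(m):
            if c in selected:
                continue
            r2_max = float(np.max(R[c, selected] ** 2))
            if r2_max > r2_cap:
                continue
            p_c = joint_p_for(c)
            if p_c is None:
                if ids[c] not in trace.skipped_collinear:
                    trace.skipped_collinear.append(ids[c])
                continue
            if best is None or p_c < best[1]:
                best = (c, p_c, r2_max)
        if best is None:
            trace.termination = "no candidate"
            return trace
        c, p_c, r2_max = best
        if p_c >= p_entry:
            trace.termination = "no p_cond below threshold"
            return trace
        selected.append(c)
        trace.selected.append(ids[c])
        trace.p_gwas[ids[c]] = float(p_marg[c])
        trace.p_cond[ids[c]] = p_c
        trace.r2_to_selected[ids[c]] = r2_max


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis
# ---------------------------------------------------------------------------

def meta_fixed(studies: list[GwasTable]) -> pd.DataFrame:
    """Inverse-variance fixed-effect meta-analysis with Cochran's Q.

    SNPs are matched by id across studies and allele frames rotated
    onto the first study's (a swapped effect/other pair flips beta and
    eaf; irreconcilable pairs drop the SNP with a count in the log).
    Single-study SNPs pass through with Q = 0 and p_het = NA (zero
    degrees of freedom).
    """
    if not studies:
        raise ValueError("need at least one study")
    frame = {}
    dropped = 0
    for si, st in enumerate(studies):
        for row in st.df.itertuples():
            key = row.snp_id
            if key not in frame:
                frame[key] = {"ea": row.effect_allele,
                              "oa": row.other_allele,
                              "chrom": row.chrom, "pos": row.pos,
                              "betas": [], "ses": []}
            rec = frame[key]
            if (row.effect_allele, row.other_allele) == (rec["ea"], rec["oa"]):
                b = row.beta
            elif (row.other_allele, row.effect_allele) == (rec["ea"],
                                                           rec["oa"]):
                b = -row.beta
            else:
                rec["betas"].append(None)
                continue
            rec["betas"].append(b)
            rec["ses"].append(row.se)

    rows = []
    for snp, rec in frame.items():
        if any(b is None for b in rec["betas"]):
            dropped += 1
            continue
        b = np.array(rec["betas"], float)
        s = np.array(rec["ses"], float)
        w = 1.0 / s ** 2
        comb = float((w * b).sum() / w.sum())
        se_comb = float(w.sum() ** -0.5)
        z = comb / se_comb
        p = float(np.clip(2 * stats.norm.sf(abs(z)),
                          np.finfo(float).tiny, 1.0))
        q = float((w * (b - comb) ** 2).sum())
        k = len(b)
        p_het = float(stats.chi2.sf(q, k - 1)) if k > 1 else np.nan
        rows.append({"snp_id": snp, "chrom": rec["chrom"], "pos": rec["pos"],
                     "effect_allele": rec["ea"], "other_allele": rec["oa"],
                     "beta": comb, "se": se_comb, "z": z, "p": p,
                     "k": k, "Q": q, "p_het": p_het,
                     "heterogeneous": (p_het < 0.05) if k > 1 else False})
    if dropped:
        logger.warning("meta_fixed: dropped %d SNPs with irreconcilable "
                       "allele frames", dropped)
    return pd.DataFrame(rows)
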