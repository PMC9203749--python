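"""Characterisation: CpG-to-gene linking and expression analyses.

Interval annotation of CpGs to gene features, a transparent
differential-expression test (median-of-ratios size factors, per-gene
OLS on log2 normalized counts, <10-total-count filter), the
distance-window selection rule (choose the flanking window before the
maximum drop in DEG proportion), eQTL/meQTL SNP-overlap enrichment with
a median-based null, the interaction (mediation) regression

    expression ~ sample_type + methylation + sample_type:methylation,

methylation/expression direction concordance, and a gene-set Fisher
test utility with Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, binom_test
from .imewas import bh_fdr
from .io_formats import AnnotationSet, OmicsMatrix

logger = logging.getLogger("methlink")

#: precedence order, highest first
CATEGORY_PRECEDENCE = [
    "splicing", "exonic", "utr5", "utr3", "ncRNA_exonic", "intronic",
    "ncRNA_intronic", "upstream", "downstream", "intergenic",
]

FLANK = 1000         # upstream/downstream window beyond the tx span (bp)
SPLICE_DIST = 2      # bp from an internal exon boundary


# ---------------------------------------------------------------------------
# interval annotation
# ---------------------------------------------------------------------------

def _categorise_in_gene(pos: int, gene: pd.Series,
                        exons: list[tuple[int, int]]) -> str | None:
    """Category of ``pos`` relative to one gene, or None if unrelated."""
    s, e = int(gene["tx_start"]), int(gene["tx_end"])
    strand = gene["strand"]
    coding = bool(gene["coding"])
    if pos < s - FLANK or pos > e + FLANK:
        return None
    if pos < s:
        return "upstream" if strand == "+" else "downstream"
    if pos > e:
        return "downstream" if strand == "+" else "upstream"
    # inside the transcript
    if coding:
        boundaries = []
        for (a, b) in exons:
            if a != s:
                boundaries.append(a)
            if b != e:
                boundaries.append(b)
        if any(abs(pos - x) <= SPLICE_DIST for x in boundaries):
            return "splicing"
    in_exon = any(a <= pos <= b for a, b in exons)
    if not coding:
        return "ncRNA_exonic" if in_exon else "ncRNA_intronic"
    if in_exon:
        cs, ce = int(gene["cds_start"]), int(gene["cds_end"])
        if pos < cs:
            return "utr5" if strand == "+" else "utr3"
        if pos > ce:
            return "utr3" if strand == "+" else "utr5"
        return "exonic"
    return "intronic"


def annotate_cpgs(cpg_positions: pd.DataFrame,
                  annotation: AnnotationSet) -> pd.DataFrame:
    """Assign every CpG a category and the overlapping gene list.

    All overlapping genes are reported; the category is the
    highest-precedence one among them, intergenic when no gene's
    extended span (tx +/- 1 kb) covers the position.
    """
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    genes = annotation.genes
    out = []
    for _, row in cpg_positions.iterrows():
        pos, chrom = int(row["pos"]), str(row["chrom"])
        if pos < 1:
            raise ValueError(f"{row['cpg_id']}: position beyond the genome")
        hits = []
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            cat = _categorise_in_gene(pos, g, annotation.gene_exons(g))
            if cat is not None:
                hits.append((cat, g["gene_id"]))
        if not hits:
            cat, gene_list = "intergenic", []
        else:
            hits.sort(key=lambda h: rank[h[0]])
            cat = hits[0][0]
            gene_list = [g for _, g in hits]
        out.append({"cpg_id": row["cpg_id"], "category": cat,
                    "genes": ",".join(gene_list)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# stand-in differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    gene_id: str
    fold_change: float  # case/control ratio of normalized means
    log2fc: float
    p: float
    fdr: float
    direction: str      # up iff fold_change > 1


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (genes x samples in)."""
    positive = counts.loc[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        raise ValueError("no gene with all-positive counts for size factors")
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0).to_numpy())


def de_test(counts: OmicsMatrix, case: str = "tumour",
            control: str = "NAT", min_total: int = 10) -> pd.DataFrame:
    """Two-group differential expression on normalized counts.

    Genes with total count below ``min_total`` are removed before
    testing; p values come from an OLS t test on
    log2(normalized count + 0.5); fold change is the ratio of
    normalized group means.
    """
    keep = counts.metadata["sample_type"].isin([case, control])
    sub = counts.subset_samples(list(counts.metadata.index[keep]))
    if (sub.metadata["sample_type"] == case).sum() < 2 or \
            (sub.metadata["sample_type"] == control).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    vals = sub.values.loc[sub.values.sum(axis=1) >= min_total]
    if len(vals) == 0:
        raise ValueError("no gene passes the count filter")
    sf = size_factors(vals)
    norm = vals / sf[None, :]
    case_mask = (sub.metadata["sample_type"] == case).to_numpy()

    mean_case = norm.loc[:, case_mask].mean(axis=1)
    mean_ctrl = norm.loc[:, ~case_mask].mean(axis=1)
    fc = mean_case / mean_ctrl

    Y = np.log2(norm.to_numpy(float) + 0.5).T  # samples x genes
    X = np.column_stack([np.ones(len(case_mask)), case_mask.astype(float)])
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = X.shape[0] - 2
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B[1] / se, np.inf * np.sign(B[1]))
    p = 2 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({
        "gene_id": vals.index,
        "fold_change": fc.to_numpy(),
        "log2fc": np.log2(fc.to_numpy()),
        "p": p,
    }).reset_index(drop=True)
    table["fdr"] = bh_fdr(table["p"])
    table["direction"] = np.where(table["fold_change"] > 1, "up", "down")
    return table


# ---------------------------------------------------------------------------
# distance-window selection
# ---------------------------------------------------------------------------

DEFAULT_WINDOWS = (1_000, 5_000, 10_000, 25_000, 50_000, 100_000,
                   500_000, 1_000_000, 5_000_000, 10_000_000)


@dataclass
class WindowScan:
    windows: list
    proportions: list       # DEG proportion per window
    enrichment_p: list      # one-sided binomial vs the null rate
    selected_window: int
    selected_degs: list


def select_window(windows, proportions) -> int:
    """Window before the maximum decrease in DEG proportion when the
    cut-off grows; ties break toward the smaller window."""
    drops = [proportions[i] - proportions[i + 1]
             for i in range(len(proportions) - 1)]
    best = int(np.argmax(drops))  # argmax takes the first (smallest) max
    return windows[best]


def distance_window_scan(cpg_positions: pd.DataFrame, de: pd.DataFrame,
                         genes: pd.DataFrame, null_rate: float,
                         windows=DEFAULT_WINDOWS,
                         fdr: float = 0.05) -> WindowScan:
    """DEG-proportion profile over growing flanking windows around the
    CpG set, with the drop-based selection rule.

    A gene counts toward window w when its span overlaps (including
    partially) [pos - w, pos + w] of any CpG.  Enrichment per window is
    a one-sided exact binomial against the genome-wide differential
    expression rate ``null_rate``.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    if not (0 < null_rate < 1):
        raise ValueError("null_rate must lie in (0, 1)")
    windows = sorted(int(w) for w in windows)
    deg = set(de.loc[de["fdr"] < fdr, "gene_id"])
    tested = de.set_index("gene_id")
    props, ps, per_window_deg = [], [], []
    for w in windows:
        members = set()
        for _, row in cpg_positions.iterrows():
            lo, hi = row["pos"] - w, row["pos"] + w
            hit = genes[(genes["chrom"] == str(row["chrom"]))
                        & (genes["tx_end"] >= lo) & (genes["tx_start"] <= hi)]
            members.update(hit["gene_id"])
        members &= set(tested.index)
        k = len(members & deg)
        n = len(members)
        props.append(k / n if n else 0.0)
        ps.append(binom_test(k, n, null_rate, "greater") if n else 1.0)
        per_window_deg.append(sorted(members & deg))
    sel = select_window(windows, props)
    sel_degs = per_window_deg[windows.index(sel)]
    return WindowScan(list(windows), props, ps, sel, sel_degs)


# ---------------------------------------------------------------------------
# eQTL overlap
# ---------------------------------------------------------------------------

def eqtl_overlap_enrichment(meqtl_models: list, eqtl_models: list,
                            fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene enrichment of a CpG set's meQTL SNPs within the gene's
    eQTL prediction SNPs.

    k = |eQTL SNPs intersect union of meQTL SNPs|, n = |eQTL SNPs|;
    the null proportion is the median k/n over genes with k >= 1;
    one-sided (greater) binomial, BH FDR.  Genes at fdr < 0.05 are the
    candidates for imputed differential expression.
    """
    meqtl_union = set()
    for m in meqtl_models:
        meqtl_union.update(m.snp_ids)
    rows = []
    for g in eqtl_models:
        n = len(g.snp_ids)
        k = len(set(g.snp_ids) & meqtl_union)
        rows.append({"gene_id": g.unit_id, "k": k, "n": n,
                     "proportion": k / n if n else 0.0})
    table = pd.DataFrame(rows)
    with_hit = table.loc[table["k"] >= 1, "proportion"]
    if len(with_hit) == 0:
        raise ValueError("no gene overlaps the meQTL SNP set; "
                         "null proportion undefined")
    p0 = float(with_hit.median())
    p0 = min(max(p0, np.finfo(float).tiny), 1 - 1e-12)
    table["p0"] = p0
    table["p"] = [binom_test(r.k, r.n, p0, "greater") if r.n else 1.0
                  for r in table.itertuples()]
    table["fdr"] = bh_fdr(table["p"])
    table["selected"] = table["fdr"] < fdr
    return table


# ---------------------------------------------------------------------------
# mediation (interaction) regression
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    gene_id: str
    cpg_id: str
    interaction: float
    p_interaction: float
    fdr: float = np.nan


def mediation_test(expression: OmicsMatrix, methylation: OmicsMatrix,
                   pairs: list[tuple[str, str]],
                   case: str = "tumour", control: str = "NAT",
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Interaction regression per CpG-gene pair on matched samples.

    log2(normalized expression + pseudocount) ~ sample_type +
    methylation + sample_type:methylation; the interaction coefficient
    carries the conditional association.  Pairs whose design is
    collinear (e.g. methylation constant within a group) give NA rows
    excluded from the FDR denominator.
    """
    shared = [s for s in expression.sample_ids
              if s in set(methylation.sample_ids)]
    meta = expression.metadata.loc[shared]
    keep = meta["sample_type"].isin([case, control])
    shared = list(meta.index[keep])
    if not shared:
        raise ValueError("no matched samples between the two matrices")
    stype = (expression.metadata.loc[shared, "sample_type"] == case
             ).to_numpy(float)
    if stype.sum() == 0 or stype.sum() == len(stype):
        raise ValueError("both groups must be present")

    counts = expression.values[shared]
    sf = size_factors(counts.loc[(counts > 0).all(axis=1)])
    norm = counts / sf[None, :]

    rows = []
    for gene, cpg in pairs:
        if gene not in norm.index or cpg not in methylation.values.index:
            logger.warning("mediation_test: pair (%s, %s) missing data, "
                           "excluded", gene, cpg)
            rows.append({"gene_id": gene, "cpg_id": cpg,
                         "interaction": np.nan, "p_interaction": np.nan})
            continue
        y = np.log2(norm.loc[gene].to_numpy(float) + pseudocount)
        m = methylation.values.loc[cpg, shared].to_numpy(float)
        if np.isnan(m).any():
            m = np.where(np.isnan(m), np.nanmedian(m), m)
        X = np.column_stack([np.ones_like(m), stype, m, stype * m])
        if np.linalg.matrix_rank(X) < 4:
            logger.warning("mediation_test: collinear design for (%s, %s)",
                           gene, cpg)
            rows.append({"gene_id": gene, "cpg_id": cpg,
                         "interaction": np.nan, "p_interaction": np.nan})
            continue
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        dof = len(y) - 4
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * XtX_inv[3, 3])
        t = b[3] / se
        p = float(np.clip(2 * stats.t.sf(abs(t), df=dof),
                          np.finfo(float).tiny, 1.0))
        rows.append({"gene_id": gene, "cpg_id": cpg,
                     "interaction": b[3], "p_interaction": p})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    tested = table["p_interaction"].notna()
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p_interaction"])
    return table


# ---------------------------------------------------------------------------
# direction concordance
# ---------------------------------------------------------------------------

def direction_concordance(dm: pd.DataFrame, de: pd.DataFrame,
                          pairs: list[tuple[str, str]]) -> dict:
    """Count negative vs positive methylation/expression coupling.

    negative = (hypo, up) or (hyper, down); positive = (hypo, down) or
    (hyper, up).  Pairs missing either result are excluded and counted.
    """
    dm_dir = dm.set_index("unit_id")["direction"].to_dict()
    de_dir = de.set_index("gene_id")["direction"].to_dict()
    neg, pos, excluded = [], [], 0
    for cpg, gene in pairs:
        d1, d2 = dm_dir.get(cpg), de_dir.get(gene)
        if pd.isna(d1) or pd.isna(d2) or d1 is None or d2 is None:
            excluded += 1
            continue
        if (d1 == "hypo") == (d2 == "up"):
            neg.append((cpg, gene))
        else:
            pos.append((cpg, gene))
    return {"negative": len(neg), "positive": len(pos),
            "negative_pairs": neg, "positive_pairs": pos,
            "excluded": excluded}


# ---------------------------------------------------------------------------
# gene-set Fisher utility
# ---------------------------------------------------------------------------

def gene_set_fisher(gene_set, pathways: dict, universe,
                    min_overlap: int = 2) -> pd.DataFrame:
    """2x2 Fisher exact test per pathway with Bonferroni adjustment.

    Pathways overlapping the gene set in fewer than ``min_overlap``
    genes are excluded before adjustment.
    """
    if not pathways:
        raise ValueError("empty pathway database")
    gene_set = set(gene_set) & set(universe)
    universe = set(universe)
    rows = []
    for name, members in pathways.items():
        members = set(members) & universe
        k = len(gene_set & members)
        if k < min_overlap:
            continue
        a = k
        b = len(gene_set) - k
        c = len(members) - k
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"pathway": name, "overlap": k, "pathway_size":
                     len(members), "p": float(p)})
    table = pd.DataFrame(rows, columns=["pathway", "overlap",
                                        "pathway_size", "p"])
    if len(table):
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    else:
        table["p_bonferroni"] = pd.Series(dtype=float)
    return table
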