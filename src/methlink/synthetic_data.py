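"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the data the analysis was
designed for: a dosage reference panel with first-order autoregressive
LD, sparse cis-SNP weight models whose genetic component explains a set
cis-heritability of methylation, GWAS summary statistics from a cohort
whose phenotype is mediated through methylation (y = sum_c gamma_c M_c
+ eps with M_c = w'g + e), tumour/NAT/healthy beta-value matrices with
age and batch structure plus planted outliers and missingness, and
negative-binomial expression counts with CpG-linked differential
expression.  A :class:`TruthSet` records every planted signal so that
downstream recovery can be scored.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng`` (PCG64) with fixed per-stage child seeds,
so identical configs give identical data on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet, GwasTable, OmicsMatrix, ReferencePanel, WeightModel,
)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]

# fixed child-seed offsets so each stage draws an independent,
# reproducible stream even when called in isolation
_STREAMS = {"panel": 1, "weights": 2, "gwas": 3, "meth": 4, "expr": 5}


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    Defaults are the study conditions the acceptance suite runs under:
    a 2000-individual GWAS cohort, 40 CpGs of which 8 are causal with a
    per-CpG phenotype effect of 0.3, a 0.15 latent tumour-control
    methylation shift, 60+60(+60) tissue samples, and 2-fold expression
    changes at CpG-linked genes.
    """

    seed: int = 0
    n_panel: int = 500          # LD reference individuals
    n_cohort: int = 2000        # GWAS cohort individuals
    m_snps: int = 300
    n_cpgs: int = 40
    n_causal: int = 8
    n_genes: int = 30
    genome_length: int = 3_000_000
    chrom: str = "1"
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.3       # adjacent-SNP haplotype copy probability
    snps_per_cpg: int = 3
    h2_meth: float = 0.3        # cis-heritability of methylation
    gamma: float = 0.3          # per-CpG effect of methylation on liability
    dm_effect: float = 0.15     # latent tumour-control beta shift
    age_effect: float = 0.01    # latent methylation slope per year
    meth_noise_sd: float = 0.15  # within-group latent noise
    batch_sd: float = 0.15      # per-batch per-CpG technical offsets
    missing_rate: float = 0.02
    n_outliers: int = 2
    n_tumour: int = 60
    n_nat: int = 60
    n_healthy: int = 60
    de_log2fc: float = 1.0
    mediation_effect: float = 8.0  # log2-expression slope difference per beta unit
    n_mediation_genes: int = 3
    nb_dispersion: float = 0.1
    n_blocks: int = 30

    def __post_init__(self):
        for name in ("n_panel", "n_cohort", "m_snps", "n_cpgs", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if not (0 < self.h2_meth < 1):
            raise ValueError("h2_meth must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must sit inside (0, 0.5]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_causal > self.n_cpgs:
            raise ValueError("n_causal cannot exceed n_cpgs")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stage]]))


@dataclass
class TruthSet:
    """Planted signals; the scoring key for recovery tests."""

    causal_cpgs: list = field(default_factory=list)
    cpg_sign: dict = field(default_factory=dict)       # cpg -> +1/-1
    weights: dict = field(default_factory=dict)        # cpg -> (snp_ids, w)
    snp_true_beta: dict = field(default_factory=dict)  # marginal E[beta]
    de_genes: list = field(default_factory=list)       # shift-only DE genes
    gene_log2fc: dict = field(default_factory=dict)
    mediation_pairs: list = field(default_factory=list)  # (gene, cpg)
    outlier_samples: list = field(default_factory=list)
    cpg_gene_link: dict = field(default_factory=dict)  # cpg -> gene
    cohort: dict = field(default_factory=dict)         # G, y, M, snp_ids


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _simulate_haplotype_dosages(rng, n_ind, freqs, ld_decay):
    """Copy-chain haplotypes: allele l+1 copies allele l with probability
    ``ld_decay``, else is a fresh Bernoulli draw.  Adjacent-SNP dosage
    correlation is ~ld_decay when neighbouring frequencies are similar."""
    m = len(freqs)
    haps = np.empty((2 * n_ind, m), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n_ind) < freqs[0]
    for l in range(1, m):
        fresh = rng.random(2 * n_ind) < freqs[l]
        copy = rng.random(2 * n_ind) < ld_decay
        haps[:, l] = np.where(copy, haps[:, l - 1], fresh)
    return (haps[0::2] + haps[1::2]).astype(float)


def simulate_panel(cfg: SimulationConfig) -> ReferencePanel:
    """LD reference panel with AR(1)-style LD and uniform MAF draws."""
    rng = cfg.rng("panel")
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, cfg.m_snps)
    positions = np.linspace(1, cfg.genome_length, cfg.m_snps + 2)[1:-1]
    positions = positions.astype(int)
    dosages = _simulate_haplotype_dosages(rng, cfg.n_panel, freqs, cfg.ld_decay)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(cfg.m_snps)]
    snps = pd.DataFrame({
        "snp_id": [f"{cfg.chrom}:{p}" for p in positions],
        "chrom": cfg.chrom,
        "pos": positions,
        "ref_allele": [a for a, _ in pairs],
        "alt_allele": [b for _, b in pairs],
    })
    samples = [f"P{i:04d}" for i in range(cfg.n_panel)]
    return ReferencePanel(samples, snps, dosages)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENE_SPAN = 6000
_CATEGORIES = ["exonic", "intronic", "utr5", "utr3", "upstream",
               "downstream", "intergenic", "splicing",
               "ncRNA_exonic", "ncRNA_intronic"]


def simulate_annotation(cfg: SimulationConfig):
    """Gene models, LD blocks, and CpG positions covering every
    annotation category.

    Genes are evenly spaced on one chromosome; every 5th gene is
    non-coding.  Coding genes have three exons with a 5'-UTR in exon 1
    and a 3'-UTR in exon 3 (plus strand; minus-strand genes mirror).
    CpGs cycle deterministically through the annotation categories so
    each category receives at least ``n_cpgs // len(categories)`` CpGs.

    Returns ``(AnnotationSet, cpg_positions)`` where ``cpg_positions``
    has columns cpg_id, chrom, pos, category_intent, linked_gene.
    """
    spacing = cfg.genome_length // (cfg.n_genes + 1)
    if spacing <= _GENE_SPAN + 4000:
        raise ValueError("genome too short to pack the requested genes")
    rows = []
    for i in range(cfg.n_genes):
        s = spacing * (i + 1)
        e = s + _GENE_SPAN - 1
        coding = (i % 5) != 4
        strand = "+" if i % 2 == 0 else "-"
        exon_starts = [s, s + 3000, s + 5000]
        exon_ends = [s + 999, s + 3999, s + 5999]
        rows.append({
            "gene_id": f"G{i:03d}", "chrom": cfg.chrom, "strand": strand,
            "tx_start": s, "tx_end": e,
            "cds_start": s + 500 if coding else 0,
            "cds_end": s + 5499 if coding else 0,
            "coding": coding,
            "exon_starts": ",".join(map(str, exon_starts)),
            "exon_ends": ",".join(map(str, exon_ends)),
        })
    genes = pd.DataFrame(rows)

    block_w = cfg.genome_length // cfg.n_blocks
    blocks = pd.DataFrame({
        "block_id": [f"B{i:03d}" for i in range(cfg.n_blocks)],
        "chrom": cfg.chrom,
        "start": [i * block_w + 1 for i in range(cfg.n_blocks)],
        "end": [(i + 1) * block_w for i in range(cfg.n_blocks)],
    })

    coding_idx = [i for i in range(cfg.n_genes) if (i % 5) != 4]
    nc_idx = [i for i in range(cfg.n_genes) if (i % 5) == 4]
    plus_coding = [i for i in coding_idx if i % 2 == 0]

    cpg_rows = []
    for j in range(cfg.n_cpgs):
        cat = _CATEGORIES[j % len(_CATEGORIES)]
        cyc = j // len(_CATEGORIES)
        if cat.startswith("ncRNA"):
            gi = nc_idx[cyc % len(nc_idx)]
        elif cat in ("utr5", "utr3", "upstream", "downstream"):
            # strand-dependent categories use plus-strand genes so the
            # intended category is unambiguous
            gi = plus_coding[cyc % len(plus_coding)]
        else:
            gi = coding_idx[cyc % len(coding_idx)]
        s = spacing * (gi + 1)
        jitter = (cyc * 7) % 50  # deterministic de-duplication
        if cat == "exonic":
            pos = s + 3400 + jitter
        elif cat == "intronic":
            pos = s + 2000 + jitter
        elif cat == "utr5":
            pos = s + 200 + jitter % 200
        elif cat == "utr3":
            pos = s + 5700 + jitter % 200
        elif cat == "upstream":
            pos = s - 500 - jitter
        elif cat == "downstream":
            pos = s + _GENE_SPAN - 1 + 500 + jitter
        elif cat == "intergenic":
            pos = s + spacing // 2 + jitter
            gi = min(gi, cfg.n_genes - 1)
        elif cat == "splicing":
            pos = s + 3000 - 1  # 1 bp before an internal exon start
        elif cat == "ncRNA_exonic":
            pos = s + 3400 + jitter
        else:  # ncRNA_intronic
            pos = s + 2000 + jitter
        cpg_rows.append({
            "cpg_id": f"cg{j:06d}", "chrom": cfg.chrom, "pos": int(pos),
            "category_intent": cat, "linked_gene": f"G{gi:03d}",
        })
    cpgs = pd.DataFrame(cpg_rows)
    if cpgs["pos"].duplicated().any():
        raise ValueError("CpG packing produced duplicate positions")
    return AnnotationSet(genes, blocks), cpgs


# ---------------------------------------------------------------------------
# weight models
# ---------------------------------------------------------------------------

def simulate_weight_models(panel: ReferencePanel, cfg: SimulationConfig,
                           cpg_positions: pd.DataFrame | None = None):
    """Sparse cis weight vectors scaled so the genetic score explains
    ``h2_meth`` of the (unit-variance) latent methylation."""
    rng = cfg.rng("weights")
    if cpg_positions is None:
        _, cpg_positions = simulate_annotation(cfg)
    truth = TruthSet()
    snp_pos = panel.snps["pos"].to_numpy()
    models = []
    for _, row in cpg_positions.iterrows():
        dist = np.abs(snp_pos - row["pos"])
        cis = np.where(dist <= 1_000_000)[0]
        if len(cis) < cfg.snps_per_cpg:
            raise ValueError(
                f"{row['cpg_id']}: only {len(cis)} cis SNPs within 1 Mb, "
                f"{cfg.snps_per_cpg} requested")
        pick = cis[np.argsort(dist[cis])[:cfg.snps_per_cpg]]
        pick = np.sort(pick)
        w = rng.normal(size=len(pick))
        score = panel.dosages[:, pick] @ w
        sd = score.std(ddof=1)
        if sd == 0:
            w = np.abs(w) + 0.5
            score = panel.dosages[:, pick] @ w
            sd = score.std(ddof=1)
        w *= np.sqrt(cfg.h2_meth) / sd
        sub = panel.snps.iloc[pick]
        entries = pd.DataFrame({
            "snp_id": sub["snp_id"].to_numpy(),
            "effect_allele": sub["alt_allele"].to_numpy(),
            "other_allele": sub["ref_allele"].to_numpy(),
            "weight": w,
        })
        models.append(WeightModel(row["cpg_id"], str(row["chrom"]),
                                  int(row["pos"]), entries))
        truth.weights[row["cpg_id"]] = (list(sub["snp_id"]), w.copy())

    causal = rng.choice(cpg_positions["cpg_id"].to_numpy(), size=cfg.n_causal,
                        replace=False)
    truth.causal_cpgs = sorted(causal.tolist())
    signs = rng.choice([-1, 1], size=cfg.n_causal)
    truth.cpg_sign = dict(zip(truth.causal_cpgs, signs.tolist()))
    truth.cpg_gene_link = dict(zip(cpg_positions["cpg_id"],
                                   cpg_positions["linked_gene"]))
    return models, truth


# ---------------------------------------------------------------------------
# GWAS cohort
# ---------------------------------------------------------------------------

def simulate_gwas(panel: ReferencePanel, models: list[WeightModel],
                  cfg: SimulationConfig, truth: TruthSet | None = None,
                  gamma: float | None = None):
    """Marginal per-SNP least-squares summary statistics on a simulated
    continuous liability.

    The cohort shares the panel's frequency/LD process.  Latent
    methylation M_c = w'g + e (unit variance), liability
    y = sum over causal c of gamma * sign_c * M_c + N(0, 1).
    Individual-level cohort data are kept on the truth set for oracle
    checks.
    """
    if cfg.n_cohort < 50:
        raise ValueError("n_cohort < 50: marginal se estimates unstable")
    if truth is None:
        truth = TruthSet()
    g = cfg.gamma if gamma is None else gamma
    rng = cfg.rng("gwas")
    freqs = panel.frequencies
    G = _simulate_haplotype_dosages(rng, cfg.n_cohort, freqs, cfg.ld_decay)
    snp_index = {s: i for i, s in enumerate(panel.snp_ids)}

    n = cfg.n_cohort
    M = {}
    y = rng.normal(size=n)  # environmental liability
    for m in models:
        idx = [snp_index[s] for s in m.snp_ids]
        gen = G[:, idx] @ m.weights
        e = rng.normal(scale=np.sqrt(1 - cfg.h2_meth), size=n)
        M[m.unit_id] = gen + e
        if m.unit_id in truth.cpg_sign:
            y = y + g * truth.cpg_sign[m.unit_id] * M[m.unit_id]

    Xc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc ** 2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    from scipy import stats
    z = beta / se
    p = 2 * stats.t.sf(np.abs(z), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    df = panel.snps[["snp_id", "chrom", "pos"]].copy()
    df["effect_allele"] = panel.snps["alt_allele"]
    df["other_allele"] = panel.snps["ref_allele"]
    df["eaf"] = G.mean(axis=0) / 2
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["n"] = n
    ok = (df["eaf"] > 0) & (df["eaf"] < 1)
    df = df.loc[ok].reset_index(drop=True)

    truth.cohort = {"G": G, "snp_ids": panel.snp_ids, "y": y, "M": M}
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "p", "n"]
    return GwasTable(df[cols]), truth


# ---------------------------------------------------------------------------
# tissue methylation study
# ---------------------------------------------------------------------------

def _squash(latent):
    return 1.0 / (1.0 + np.exp(-latent))


def simulate_methylation_study(models: list[WeightModel],
                               cfg: SimulationConfig,
                               truth: TruthSet | None = None) -> tuple:
    """Tumour / NAT / healthy beta-value matrix.

    Latent Gaussian per CpG and sample: baseline + age slope + group
    batch offset + (tumour only, causal CpGs) dm_effect * sign + noise,
    squashed through a logistic into [0, 1].  Causal CpGs sit at an
    intermediate baseline (beta ~ 0.5) where array variability is
    maximal.  ~2% of entries are set missing; ``n_outliers`` samples get
    a uniform latent shift and are recorded on the truth set.
    """
    if truth is None:
        truth = TruthSet()
    rng = cfg.rng("meth")
    groups = (["tumour"] * cfg.n_tumour + ["NAT"] * cfg.n_nat
              + ["healthy"] * cfg.n_healthy)
    samples = [f"S{i:04d}" for i in range(len(groups))]
    ages = rng.uniform(40, 70, len(groups))
    cpg_ids = [m.unit_id for m in models]
    n_c, n_s = len(cpg_ids), len(samples)

    base = rng.normal(size=n_c)
    causal_mask = np.array([c in truth.cpg_sign for c in cpg_ids])
    base[causal_mask] = 0.0
    signs = np.array([truth.cpg_sign.get(c, 0) for c in cpg_ids], float)

    # processing batches alternate across samples (orthogonal to sample
    # type by construction) so PC covariates have technical structure to
    # remove without absorbing the biological contrast
    batches = np.arange(n_s) % 2
    batch_shift = rng.normal(scale=cfg.batch_sd, size=(n_c, 2))
    latent = np.tile(base[:, None], (1, n_s))
    latent += cfg.age_effect * (ages - 55.0)[None, :]
    latent += batch_shift[:, batches]
    tumour_mask = np.array([g == "tumour" for g in groups])
    latent[:, tumour_mask] += (cfg.dm_effect * signs)[:, None]
    latent += rng.normal(scale=cfg.meth_noise_sd, size=(n_c, n_s))

    # planted outliers: one per group in turn, uniform latent shift
    out_ids = []
    group_order = ["tumour", "NAT", "healthy"]
    for k in range(cfg.n_outliers):
        gname = group_order[k % len(group_order)]
        cand = [i for i, g in enumerate(groups) if g == gname]
        si = cand[k % len(cand)]
        latent[:, si] += 2.0
        out_ids.append(samples[si])
    truth.outlier_samples = out_ids

    beta = _squash(latent)
    miss = rng.random((n_c, n_s)) < cfg.missing_rate
    beta = np.where(miss, np.nan, beta)

    values = pd.DataFrame(beta, index=cpg_ids, columns=samples)
    meta = pd.DataFrame({"sample_type": groups, "age": ages,
                         "group": [f"batch{b}" for b in batches]},
                        index=samples)
    return OmicsMatrix(values, meta, kind="methylation"), truth


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimulationConfig, truth: TruthSet,
                        meth: OmicsMatrix,
                        annotation: AnnotationSet) -> tuple:
    """Negative-binomial gene counts for the tumour + NAT samples.

    Genes linked to causal CpGs are differentially expressed: most get a
    pure tumour shift of ``de_log2fc`` with sign opposite to the CpG's
    methylation direction (promoter-style negative coupling); the last
    ``n_mediation_genes`` instead get a tumour-specific log2-expression
    slope on the observed CpG beta value (group means untouched), so the
    interaction regression has a planted signal to recover.  Library
    sizes vary x[0.5, 2].
    """
    rng = cfg.rng("expr")
    keep = meth.metadata["sample_type"].isin(["tumour", "NAT"])
    samples = list(meth.metadata.index[keep])
    tumour = (meth.metadata.loc[samples, "sample_type"] == "tumour").to_numpy()

    gene_ids = list(annotation.genes["gene_id"])
    n_g, n_s = len(gene_ids), len(samples)
    log2_mu0 = rng.uniform(6, 9, n_g)
    libsize = rng.uniform(0.5, 2.0, n_s)

    causal = [c for c in truth.causal_cpgs]
    med_cpgs = causal[-cfg.n_mediation_genes:] if cfg.n_mediation_genes else []
    shift_cpgs = [c for c in causal if c not in med_cpgs]

    log2fc = np.zeros(n_g)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    truth.de_genes, truth.mediation_pairs = [], []
    for c in shift_cpgs:
        g = truth.cpg_gene_link[c]
        if g in gidx:
            fc = -truth.cpg_sign[c] * cfg.de_log2fc
            log2fc[gidx[g]] = fc
            truth.de_genes.append(g)
            truth.gene_log2fc[g] = fc

    interaction = np.zeros((n_g, n_s))
    beta_obs = meth.values[samples]
    for c in med_cpgs:
        g = truth.cpg_gene_link[c]
        if g not in gidx:
            continue
        b = beta_obs.loc[c].to_numpy(float)
        b = np.where(np.isnan(b), np.nanmean(b), b)
        centred = b - b[tumour].mean()
        interaction[gidx[g], tumour] = cfg.mediation_effect * centred[tumour]
        truth.mediation_pairs.append((g, c))

    log2_mu = (log2_mu0[:, None] + log2fc[:, None] * tumour[None, :]
               + interaction)
    mu = (2.0 ** log2_mu) * libsize[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    values = pd.DataFrame(counts, index=gene_ids, columns=samples)
    meta = meth.metadata.loc[samples].copy()
    return OmicsMatrix(values, meta, kind="expression"), truth


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything one pipeline run consumes, plus the truth set."""

    cfg: SimulationConfig
    panel: ReferencePanel
    annotation: AnnotationSet
    cpg_positions: pd.DataFrame
    models: list
    gwas: GwasTable
    methylation: OmicsMatrix
    expression: OmicsMatrix
    truth: TruthSet


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate every pipeline input under one config/seed."""
    panel = simulate_panel(cfg)
    annotation, cpgs = simulate_annotation(cfg)
    models, truth = simulate_weight_models(panel, cfg, cpgs)
    gwas, truth = simulate_gwas(panel, models, cfg, truth)
    meth, truth = simulate_methylation_study(models, cfg, truth)
    expr, truth = simulate_expression(cfg, truth, meth, annotation)
    return SimulatedStudy(cfg, panel, annotation, cpgs, models, gwas,
                          meth, expr, truth)


def config_to_yaml_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d
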