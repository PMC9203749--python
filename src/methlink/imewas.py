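"""Summary-statistics methylome-wide association (i-MeWAS).

The imputed differential-methylation Z score for a CpG with cis weights
w, reference LD covariance Sigma, and GWAS marginals (beta_l, se_l):

    Z = sum_l  w_l * (sigma_l / sigma_g) * (beta_l / se_l),
    sigma_g = sqrt(w' Sigma w)

i.e. the MetaXcan-style linear combination of SNP weights, LD structure
and GWAS effects.  Per-SNP sd sigma_l and Sigma come from the reference
panel (empirical, denominator n-1), not from GWAS allele frequencies.
The same statistic is reused for imputed differential expression with
eQTL weights (``analysis_tag='eqtl_de'``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ASSOC_COLUMNS, GwasTable, ReferencePanel, WeightModel

logger = logging.getLogger("methlink")

SIGMA_TOL = 1e-8


@dataclass
class LdMatrix:
    """Empirical covariance / correlation of panel dosage columns."""

    snp_ids: list
    sigma: np.ndarray  # covariance, per-SNP variances on the diagonal
    corr: np.ndarray

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.sigma[np.ix_(idx, idx)]


def ld_matrix(panel: ReferencePanel, snp_ids) -> LdMatrix:
    """Covariance (ddof=1) and correlation among the requested SNPs, in
    the requested order.  Missing SNPs are fatal."""
    D = panel.columns(snp_ids)  # raises KeyError listing the ids
    if D.shape[1] == 1:
        sigma = np.array([[D[:, 0].var(ddof=1)]])
    else:
        sigma = np.cov(D, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return LdMatrix(list(snp_ids), sigma, corr)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mewas_z(model: WeightModel, gwas: GwasTable, ld: LdMatrix):
    """One association row for one weight model.

    Model SNPs absent from the GWAS are dropped (partial-model
    imputation); the coverage fraction is reported.  Returns ``None``
    when no SNP remains or sigma_g falls below tolerance (untestable
    model, logged).
    """
    merged = model.entries.merge(gwas.df[["snp_id", "beta", "se"]],
                                 on="snp_id", how="inner")
    n_model = len(model.entries)
    if len(merged) < 1:
        logger.warning("model %s: no SNPs left after GWAS intersection",
                       model.unit_id)
        return None
    snps = list(merged["snp_id"])
    w = merged["weight"].to_numpy(float)
    sigma = ld.submatrix(snps)
    sigma_l = np.sqrt(np.diag(sigma))
    sigma_g = float(np.sqrt(max(w @ sigma @ w, 0.0)))
    if sigma_g <= SIGMA_TOL:
        logger.warning("model %s: sigma_g ~ 0, untestable model skipped",
                       model.unit_id)
        return None
    z = float(np.sum(w * sigma_l / sigma_g
                     * merged["beta"].to_numpy() / merged["se"].to_numpy()))
    p = float(2 * stats.norm.sf(abs(z)))
    return {
        "unit_id": model.unit_id,
        "z": z,
        "p": max(p, np.finfo(float).tiny),
        "sigma_g": sigma_g,
        "n_snps_used": len(snps),
        "coverage": len(snps) / n_model,
    }


def run_imewas(models: list[WeightModel], gwas: GwasTable,
               panel: ReferencePanel,
               analysis_tag: str = "imewas") -> pd.DataFrame:
    """Association table over all testable models, with BH FDR.

    The significant set downstream is fdr < 0.05.  Zero testable models
    is fatal.
    """
    rows = []
    for m in models:
        present = [s for s in m.snp_ids if s in panel._index]
        if not present:
            logger.warning("model %s: no SNPs in panel", m.unit_id)
            continue
        sub = WeightModel(m.unit_id, m.unit_chrom, m.unit_pos,
                          m.entries[m.entries["snp_id"].isin(present)]
                          .reset_index(drop=True))
        row = mewas_z(sub, gwas, ld_matrix(panel, sub.snp_ids))
        if row is not None:
            rows.append(row)
    if not rows:
        raise ValueError("no testable weight models")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"])
    table["direction"] = np.where(table["z"] < 0, "hypo", "hyper")
    table["analysis"] = analysis_tag
    return table[ASSOC_COLUMNS + ["coverage"]]
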