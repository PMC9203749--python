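"""Conventional differential methylation from observed beta values.

QC (per-group missingness threshold + median imputation), one-shot PC1
box-plot outlier removal per sample group, and the per-CpG linear model

    beta ~ sample_type + age + age^2 + top principal components

with the sample-type coefficient tested by a two-sided t test and
converted to a signed z (so downstream p = 2*Phi(-|z|) holds exactly).
PCs are computed on the post-QC, post-outlier combined case+control
matrix of the specific contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .imewas import bh_fdr
from .io_formats import ASSOC_COLUMNS, OmicsMatrix

logger = logging.getLogger("methlink")


def qc_and_impute(matrix: OmicsMatrix, max_missing: float = 0.10) -> OmicsMatrix:
    """Remove CpGs missing in more than ``max_missing`` of the samples of
    any sample group; set remaining gaps to the CpG's median."""
    vals = matrix.values
    groups = matrix.metadata["sample_type"]
    drop = pd.Series(False, index=vals.index)
    for g in groups.unique():
        cols = groups.index[groups == g]
        frac = vals[cols].isna().mean(axis=1)
        drop |= frac > max_missing
    kept = vals.loc[~drop]
    if len(kept) == 0:
        raise ValueError("QC removed every CpG")
    if drop.any():
        logger.info("qc_and_impute: removed %d CpGs over the %.0f%% "
                    "missingness threshold", int(drop.sum()), 100 * max_missing)
    med = kept.median(axis=1)
    imputed = kept.T.fillna(med).T
    return OmicsMatrix(imputed, matrix.metadata.copy(), kind=matrix.kind)


def _pc_scores(values: pd.DataFrame, k: int) -> np.ndarray:
    """Sample scores of the top-k PCs of the centred beta matrix."""
    X = values.to_numpy(float).T  # samples x CpGs
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(S))
    return U[:, :k] * S[:k]


def pc1_outlier_removal(matrix: OmicsMatrix, whisker: float = 1.5):
    """Drop samples whose PC1 score falls outside the box-plot whiskers
    [Q1 - w*IQR, Q3 + w*IQR] of their own sample group.

    Removal is performed once (no iteration); groups smaller than 4 are
    skipped with a warning.  Returns ``(matrix, removed_sample_ids)``.
    """
    pc1 = _pc_scores(matrix.values, 1)[:, 0]
    groups = matrix.metadata["sample_type"].to_numpy()
    samples = np.array(matrix.sample_ids)
    removed = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 4:
            logger.warning("pc1_outlier_removal: group %r has %d samples, "
                           "skipped", g, int(mask.sum()))
            continue
        q1, q3 = np.percentile(pc1[mask], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
        out = mask & ((pc1 < lo) | (pc1 > hi))
        removed.extend(samples[out].tolist())
    keep = [s for s in matrix.sample_ids if s not in set(removed)]
    return matrix.subset_samples(keep), removed


def dm_test(matrix: OmicsMatrix, case: str, control: str, n_pcs: int = 5,
            analysis_tag: str = "tn_dm") -> pd.DataFrame:
    """Per-CpG OLS of beta on sample type + age + age^2 + top PCs.

    Constant CpGs give NA rows excluded from the FDR denominator.
    Direction is hyper when the case-group coefficient is positive.
    """
    keep = matrix.metadata["sample_type"].isin([case, control])
    sub = matrix.subset_samples(list(matrix.metadata.index[keep]))
    meta = sub.metadata
    if (meta["sample_type"] == case).sum() == 0 or \
            (meta["sample_type"] == control).sum() == 0:
        raise ValueError("both case and control groups must be non-empty")

    stype = (meta["sample_type"] == case).to_numpy(float)
    age = meta["age"].to_numpy(float)
    pcs = _pc_scores(sub.values, n_pcs) if n_pcs > 0 else \
        np.empty((len(meta), 0))
    X = np.column_stack([np.ones_like(age), stype, age - age.mean(),
                         (age - age.mean()) ** 2, pcs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    Y = sub.values.to_numpy(float).T  # samples x CpGs
    const = np.nanstd(Y, axis=0) == 0
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B[1] / se
    p = 2 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # signed z consistent with the two-sided p
    z = np.sign(tstat) * stats.norm.isf(p / 2)

    table = pd.DataFrame({
        "unit_id": sub.feature_ids,
        "z": z, "p": p,
    })
    table.loc[const, ["z", "p"]] = np.nan
    if const.any():
        logger.info("dm_test: %d constant CpGs reported as NA",
                    int(const.sum()))
    table["fdr"] = np.nan
    tested = ~table["p"].isna()
    table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"])
    table["direction"] = np.where(table["z"] < 0, "hypo", "hyper")
    table.loc[~tested, "direction"] = pd.NA
    table["n_snps_used"] = 0
    table["sigma_g"] = np.nan
    table["analysis"] = analysis_tag
    return table[ASSOC_COLUMNS]


def dm_analysis(matrix: OmicsMatrix, case: str, control: str,
                n_pcs: int = 5, max_missing: float = 0.10,
                whisker: float = 1.5, analysis_tag: str = "tn_dm"):
    """QC -> PC1 outlier removal -> per-CpG regression, in one call.

    Returns ``(AssociationTable, removed_samples)``.
    """
    keep = matrix.metadata["sample_type"].isin([case, control])
    sub = matrix.subset_samples(list(matrix.metadata.index[keep]))
    sub = qc_and_impute(sub, max_missing=max_missing)
    sub, removed = pc1_outlier_removal(sub, whisker=whisker)
    table = dm_test(sub, case, control, n_pcs=n_pcs,
                    analysis_tag=analysis_tag)
    return table, removed
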