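"""End-to-end discovery -> overlap -> characterisation convenience layer.

Glues the per-module operations into the three-step procedure: run the
imputation-based discovery plus the tissue DM contrasts, cascade the
overlaps, and score the enriched set against a truth set when one is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffmeth import dm_analysis
from .enrichment import stepwise_enrichment
from .imewas import run_imewas
from .synthetic_data import SimulatedStudy


@dataclass
class PipelineResult:
    imewas: pd.DataFrame
    th_dm: pd.DataFrame | None
    tn_dm: pd.DataFrame
    enriched: set
    trace: list
    removed_samples: dict = field(default_factory=dict)


def run_pipeline(study: SimulatedStudy, n_pcs: int = 2,
                 fdr: float = 0.05, alpha: float = 0.05,
                 include_th: bool = True) -> PipelineResult:
    """Discovery + overlap on a simulated study.

    ``include_th=False`` mirrors the single-contrast mode used when no
    healthy tissue is available (one cascade iteration against TN-DM).
    """
    assoc = run_imewas(study.models, study.gwas, study.panel)
    tn, rm_tn = dm_analysis(study.methylation, "tumour", "NAT",
                            n_pcs=n_pcs, analysis_tag="tn_dm")
    removed = {"tn_dm": rm_tn}
    th = None
    others = []
    if include_th:
        th, rm_th = dm_analysis(study.methylation, "tumour", "healthy",
                                n_pcs=n_pcs, analysis_tag="th_dm")
        removed["th_dm"] = rm_th
        others.append(th)
    others.append(tn)
    enriched, trace = stepwise_enrichment(assoc, others, fdr=fdr,
                                          alpha=alpha)
    return PipelineResult(assoc, th, tn, enriched, trace, removed)


def score_against_truth(enriched: set, truth) -> dict:
    """Sensitivity and false discovery proportion of an enriched CpG set
    against the planted causal set."""
    causal = set(truth.causal_cpgs)
    tp = len(enriched & causal)
    sens = tp / len(causal) if causal else float("nan")
    fdp = (len(enriched) - tp) / len(enriched) if enriched else 0.0
    return {"sensitivity": sens, "fdp": fdp,
            "n_enriched": len(enriched), "n_causal": len(causal)}
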