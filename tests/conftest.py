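import numpy as np
import pandas as pd
import pytest

from methlink import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One simulated study under the default conditions."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Fully null study: no phenotype effect, no tissue DM, no DE."""
    cfg = SimulationConfig(seed=12, gamma=0.0, dm_effect=0.0,
                           de_log2fc=0.0, mediation_effect=0.0)
    return simulate_study(cfg)


def make_gwas_df(snp_ids, betas, ses, eafs=None, pos=None, n=1000,
                 chrom="1", ea="A", oa="G"):
    """Minimal valid GWAS frame for closed-form tests."""
    from scipy import stats

    m = len(snp_ids)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    z = betas / ses
    return pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eafs if eafs is not None else np.full(m, 0.3),
        "beta": betas, "se": ses,
        "p": 2 * stats.norm.sf(np.abs(z)),
        "n": n,
    })
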