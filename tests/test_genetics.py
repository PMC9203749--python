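"""FRR apportionment, LD utilities, region classes, conditional scan and
fixed-effect meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methlink import (
    FrrConfig, GwasTable, ReferencePanel, classify_region,
    conditional_scan, frr_contribution, group_cpgs_by_window,
    ld_block_assign, ld_r2, meta_fixed, pleiotropy_link,
)
from conftest import make_gwas_df


class TestFrr:
    def test_single_snp_direct_substitution(self):
        df = make_gwas_df(["s1"], [0.1], [1e-9], eafs=[0.5])
        df["se"] = 0.0  # tau = 0 in the closed form
        val = frr_contribution(df, FrrConfig(2.0))
        assert val == pytest.approx(0.25 * 0.01 / np.log(2), rel=1e-6)

    def test_beta_equals_tau_vanishes(self):
        df = make_gwas_df(["s1"], [0.05], [0.05], eafs=[0.2])
        assert frr_contribution(df, FrrConfig(2.5)) == pytest.approx(0.0)

    def test_additivity_over_snps(self):
        a = make_gwas_df(["s1"], [0.1], [0.02], eafs=[0.3])
        b = make_gwas_df(["s2"], [-0.2], [0.03], eafs=[0.1])
        both = pd.concat([a, b], ignore_index=True)
        cfg = FrrConfig(2.0)
        assert frr_contribution(both, cfg) == pytest.approx(
            frr_contribution(a, cfg) + frr_contribution(b, cfg))

    def test_allele_flip_invariance(self):
        df = make_gwas_df(["s1"], [0.1], [0.02], eafs=[0.3])
        flipped = df.copy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        cfg = FrrConfig(2.0)
        assert frr_contribution(df, cfg) == pytest.approx(
            frr_contribution(flipped, cfg))

    def test_factor2_doubles(self):
        df = make_gwas_df(["s1"], [0.1], [0.02], eafs=[0.3])
        cfg = FrrConfig(2.0)
        assert frr_contribution(df, cfg, factor2=True) == pytest.approx(
            2 * frr_contribution(df, cfg))

    def test_lambda_at_most_one_fatal(self):
        with pytest.raises(ValueError):
            FrrConfig(1.0)


def _panel(dosages, ids):
    snps = pd.DataFrame({"snp_id": ids, "chrom": "1",
                         "pos": np.arange(1, len(ids) + 1) * 1000,
                         "ref_allele": "G", "alt_allele": "A"})
    return ReferencePanel([f"i{k}" for k in range(dosages.shape[0])],
                          snps, dosages)


class TestLdR2:
    def test_identical_columns_r2_one_and_symmetry(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, 500).astype(float)
        other = rng.binomial(2, 0.3, 500).astype(float)
        panel = _panel(np.column_stack([col, col, other]),
                       ["a", "b", "c"])
        assert ld_r2(panel, "a", "b") == pytest.approx(1.0)
        assert ld_r2(panel, "a", "c") == ld_r2(panel, "c", "a")

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, (1000, 2)).astype(float)
        panel = _panel(d, ["a", "b"])
        assert ld_r2(panel, "a", "b") < 0.02


class TestClassifyRegion:
    def _gwas_with_min_p(self, pmin):
        df = make_gwas_df(["s1", "s2"], [0.1, 0.05], [0.02, 0.02],
                          pos=[500_000, 600_000])
        df["p"] = [pmin, 0.5]
        return GwasTable(df)

    @pytest.mark.parametrize("pmin,expected", [
        (4e-8, "genome_wide_significant"),
        (5e-8, "genome_wide_significant"),   # boundary inclusive
        (5e-7, "suggestive"),
        (1e-5, "suggestive"),                # boundary inclusive
        (1e-4, "novel"),
    ])
    def test_boundaries_as_printed(self, pmin, expected):
        gwas = self._gwas_with_min_p(pmin)
        assert classify_region("1", 550_000, gwas) == expected

    def test_empty_window_is_novel(self):
        gwas = self._gwas_with_min_p(1e-9)
        assert classify_region("1", 50_000_000, gwas) == "novel"


class TestConditionalScan:
    def _independent_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n, m = 2000, 4
        G = rng.binomial(2, 0.4, (n, m)).astype(float)
        y = 0.2 * G[:, 0] - 0.2 * G[:, 2] + rng.normal(size=n)
        Xc = G - G.mean(0)
        yc = y - y.mean()
        sxx = (Xc ** 2).sum(0)
        beta = Xc.T @ yc / sxx
        s2 = (yc @ yc - beta * (Xc.T @ yc)) / (n - 2)
        se = np.sqrt(s2 / sxx)
        p = 2 * stats.t.sf(np.abs(beta / se), n - 2)
        ids = [f"s{i}" for i in range(m)]
        gdf = make_gwas_df(ids, beta, se, eafs=G.mean(0) / 2, n=n)
        gdf["p"] = p
        return GwasTable(gdf), _panel(G, ids), ids, p

    def test_orthogonal_causal_snps_both_selected(self):
        gwas, panel, ids, p_marg = self._independent_setup()
        trace = conditional_scan(ids, gwas, panel)
        assert {"s0", "s2"} <= set(trace.selected)
        # conditioning on an orthogonal SNP is a no-op
        for s in ("s0", "s2"):
            i = ids.index(s)
            lm = -np.log10(p_marg[i])
            lc = -np.log10(trace.p_cond[s])
            assert abs(lc - lm) / lm < 0.1

    def test_first_selection_has_marginal_p(self):
        gwas, panel, ids, p_marg = self._independent_setup(1)
        trace = conditional_scan(ids, gwas, panel)
        first = trace.selected[0]
        assert trace.p_cond[first] == pytest.approx(
            trace.p_gwas[first])

    def test_duplicate_snp_never_selected(self):
        rng = np.random.default_rng(2)
        n = 2000
        g = rng.binomial(2, 0.4, n).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.4, n)])
        y = 0.3 * g + rng.normal(size=n)
        Xc = G - G.mean(0)
        yc = y - y.mean()
        sxx = (Xc ** 2).sum(0)
        beta = Xc.T @ yc / sxx
        s2 = (yc @ yc - beta * (Xc.T @ yc)) / (n - 2)
        se = np.sqrt(s2 / sxx)
        ids = ["dupA", "dupB", "null"]
        gdf = make_gwas_df(ids, beta, se, eafs=G.mean(0) / 2, n=n)
        gdf["p"] = 2 * stats.t.sf(np.abs(beta / se), n - 2)
        trace = conditional_scan(ids, GwasTable(gdf), _panel(G, ids))
        assert not {"dupA", "dupB"} <= set(trace.selected)

    def test_no_entry_termination(self):
        gwas, panel, ids, _ = self._independent_setup(3)
        df = gwas.df.copy()
        df["p"] = 0.5
        trace = conditional_scan(ids, GwasTable(df), panel)
        assert trace.selected == [] and trace.termination == "no entry"

    def test_selected_pairs_below_r2_cap(self):
        gwas, panel, ids, _ = self._independent_setup(4)
        trace = conditional_scan(ids, gwas, panel)
        assert all(r2 <= 0.9 for r2 in trace.r2_to_selected.values())


class TestGrouping:
    def test_cpgs_within_window_pooled(self):
        pos = pd.DataFrame({"cpg_id": ["a", "b", "c"], "chrom": "1",
                            "pos": [100_000, 900_000, 5_000_000]})
        regions = group_cpgs_by_window(pos)
        assert regions == [["a", "b"], ["c"]]


class TestMetaFixed:
    def _study(self, betas, ses, ids=("s1",), ea="A", oa="G"):
        return GwasTable(make_gwas_df(list(ids), betas, ses, ea=ea, oa=oa))

    def test_identical_studies_shrink_se_by_sqrt_k(self):
        s = self._study([0.1], [0.05])
        out = meta_fixed([s, s])
        row = out.iloc[0]
        assert row["beta"] == pytest.approx(0.1)
        assert row["se"] == pytest.approx(0.05 / np.sqrt(2))
        assert row["Q"] == pytest.approx(0.0)
        assert row["p_het"] == pytest.approx(1.0)

    def test_opposite_effects_cancel_with_q(self):
        a = self._study([0.2], [0.05])
        b = self._study([-0.2], [0.05])
        out = meta_fixed([a, b]).iloc[0]
        assert out["beta"] == pytest.approx(0.0)
        assert out["Q"] == pytest.approx(2 * 0.2 ** 2 / 0.05 ** 2)

    def test_single_study_passthrough(self):
        out = meta_fixed([self._study([0.1], [0.05])]).iloc[0]
        assert out["beta"] == pytest.approx(0.1)
        assert out["Q"] == pytest.approx(0.0)
        assert np.isnan(out["p_het"])

    def test_swapped_alleles_harmonized(self):
        a = self._study([0.2], [0.05], ea="A", oa="G")
        b = self._study([-0.2], [0.05], ea="G", oa="A")
        out = meta_fixed([a, b]).iloc[0]
        assert out["beta"] == pytest.approx(0.2)
        assert out["Q"] == pytest.approx(0.0)

    def test_irreconcilable_alleles_dropped(self):
        a = self._study([0.2], [0.05], ea="A", oa="G")
        b = self._study([0.2], [0.05], ea="C", oa="T")
        out = meta_fixed([a, b])
        assert len(out) == 0

    def test_combined_se_bounded_by_min_study_se(self):
        a = self._study([0.1], [0.05])
        b = self._study([0.3], [0.2])
        out = meta_fixed([a, b]).iloc[0]
        assert out["se"] <= 0.05


class TestPleiotropy:
    def test_shared_snp_links(self):
        rng = np.random.default_rng(0)
        panel = _panel(rng.binomial(2, 0.3, (100, 2)).astype(float),
                       ["a", "b"])
        linked, pairs = pleiotropy_link(["a", "x"], ["a", "y"], panel)
        assert linked and ("a", "a", 1.0) in pairs

    def test_moderate_ld_links(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, 2000).astype(float)
        noisy = np.clip(g + (rng.random(2000) < 0.15) *
                        rng.choice([-1, 1], 2000), 0, 2)
        panel = _panel(np.column_stack([g, noisy]), ["a", "b"])
        assert ld_r2(panel, "a", "b") > 0.4
        linked, pairs = pleiotropy_link(["a"], ["b"], panel)
        assert linked and pairs[0][2] > 0.4

    def test_low_ld_no_shared_not_linked(self):
        rng = np.random.default_rng(2)
        panel = _panel(rng.binomial(2, 0.3, (1000, 2)).astype(float),
                       ["a", "b"])
        linked, pairs = pleiotropy_link(["a"], ["b"], panel)
        assert not linked and pairs == []

    def test_empty_set_not_linked(self):
        rng = np.random.default_rng(3)
        panel = _panel(rng.binomial(2, 0.3, (50, 1)).astype(float), ["a"])
        assert pleiotropy_link([], ["a"], panel) == (False, [])


class TestLdBlocks:
    def test_assignment_and_occupancy(self):
        blocks = pd.DataFrame({"block_id": ["b1", "b2"], "chrom": "1",
                               "start": [1, 1001], "end": [1000, 2000]})
        cpgs = pd.DataFrame({"cpg_id": ["x", "y", "z"], "chrom": "1",
                             "pos": [500, 1500, 99_999]})
        assignment, occupancy = ld_block_assign(cpgs, blocks)
        assert assignment == {"x": "b1", "y": "b2", "z": "unassigned"}
        assert sum(occupancy.values()) == 2
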