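"""CpG annotation, stand-in DE, window selection, eQTL overlap,
mediation regression and concordance counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methlink import (
    OmicsMatrix, WeightModel, annotate_cpgs, de_test,
    direction_concordance, distance_window_scan, eqtl_overlap_enrichment,
    gene_set_fisher, mediation_test, select_window,
)


class TestAnnotateCpgs:
    def test_intended_categories_recovered(self, study):
        """Cross-module check: the generator's intended category equals
        the interval annotator's output for every CpG."""
        ann = annotate_cpgs(study.cpg_positions, study.annotation)
        merged = study.cpg_positions.merge(ann, on="cpg_id")
        mism = merged[merged["category_intent"] != merged["category"]]
        assert len(mism) == 0, mism.to_string()

    def test_splicing_precedence_near_exon_boundary(self, study):
        g = study.annotation.genes.iloc[0]
        pos = int(str(g["exon_starts"]).split(",")[1]) - 1
        cpgs = pd.DataFrame({"cpg_id": ["x"], "chrom": [g["chrom"]],
                             "pos": [pos]})
        ann = annotate_cpgs(cpgs, study.annotation)
        assert ann.loc[0, "category"] == "splicing"

    def test_upstream_is_strand_aware(self, study):
        minus = study.annotation.genes.query("strand == '-' and coding")
        g = minus.iloc[0]
        # 500 bp beyond tx_end on a minus-strand gene is 5' of the TSS
        cpgs = pd.DataFrame({"cpg_id": ["x"], "chrom": [g["chrom"]],
                             "pos": [int(g["tx_end"]) + 500]})
        ann = annotate_cpgs(cpgs, study.annotation)
        assert ann.loc[0, "category"] == "upstream"

    def test_position_outside_genome_fatal(self, study):
        cpgs = pd.DataFrame({"cpg_id": ["x"], "chrom": ["1"], "pos": [-5]})
        with pytest.raises(ValueError):
            annotate_cpgs(cpgs, study.annotation)


def _counts_matrix(counts, groups):
    n = counts.shape[1]
    cols = [f"s{i}" for i in range(n)]
    vals = pd.DataFrame(counts, index=[f"g{i}" for i in
                                       range(counts.shape[0])], columns=cols)
    meta = pd.DataFrame({"sample_type": groups,
                         "age": np.linspace(40, 70, n)}, index=cols)
    return OmicsMatrix(vals, meta, kind="expression")


class TestDeTest:
    def test_doubled_counts_equal_libraries_fold_change_two(self):
        # constant per-gene counts: size factors are exactly one
        base = np.repeat(np.arange(50, 150, 10)[:, None], 6, axis=1)
        counts = np.column_stack([base, base])  # identical libraries
        counts[0, :6] = base[0, :6] * 2  # doubled in cases
        m = _counts_matrix(counts, ["tumour"] * 6 + ["NAT"] * 6)
        de = de_test(m).set_index("gene_id")
        assert de.loc["g0", "fold_change"] == pytest.approx(2.0)

    def test_low_count_gene_filtered(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 200, (5, 8))
        counts[2] = [1, 1, 1, 1, 1, 1, 1, 2]  # total 9 < 10
        m = _counts_matrix(counts, ["tumour"] * 4 + ["NAT"] * 4)
        de = de_test(m)
        assert "g2" not in set(de["gene_id"])

    def test_library_rescale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(20, 400, (20, 12))
        m = _counts_matrix(counts, ["tumour"] * 6 + ["NAT"] * 6)
        de1 = de_test(m).set_index("gene_id")
        scale = np.array([1, 2, 4, 1, 2, 4, 1, 2, 4, 1, 2, 4])
        m2 = _counts_matrix((counts * scale[None, :]),
                            ["tumour"] * 6 + ["NAT"] * 6)
        de2 = de_test(m2).set_index("gene_id")
        np.testing.assert_allclose(de1["fold_change"], de2["fold_change"],
                                   rtol=1e-10)

    def test_null_p_uniform(self, null_study):
        de = de_test(null_study.expression)
        ks = stats.kstest(de["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_injected_fold_change_recovered(self, study):
        de = de_test(study.expression).set_index("gene_id")
        truth = study.truth
        folded = [de.loc[g, "fold_change"] if truth.gene_log2fc[g] > 0
                  else 1 / de.loc[g, "fold_change"]
                  for g in truth.de_genes]
        assert 1.7 <= np.mean(folded) <= 2.3


class TestWindowScan:
    def test_selection_rule_max_drop(self):
        windows = [1_000, 10_000, 25_000, 50_000]
        props = [0.70, 0.65, 0.64, 0.53]
        assert select_window(windows, props) == 25_000

    def test_printed_profile_selects_10kb(self):
        # drop from 10 kb (54.35%) to 25 kb (43.75%) is the maximum
        windows = [1_000, 5_000, 10_000, 25_000, 50_000]
        props = [0.60, 0.58, 0.5435, 0.4375, 0.40]
        assert select_window(windows, props) == 10_000

    def test_flat_profile_ties_to_smallest(self):
        assert select_window([1000, 5000, 10000], [0.5, 0.5, 0.5]) == 1000

    def test_deg_sets_monotone_in_window(self, study):
        de = de_test(study.expression)
        enriched_pos = study.cpg_positions[
            study.cpg_positions["cpg_id"].isin(study.truth.causal_cpgs)]
        rate = max(min((de["fdr"] < 0.05).mean(), 0.99), 0.01)
        scan = distance_window_scan(enriched_pos, de,
                                    study.annotation.genes, rate,
                                    windows=(1_000, 50_000, 500_000))
        sets = []
        for w in scan.windows:
            s = distance_window_scan(enriched_pos, de,
                                     study.annotation.genes, rate,
                                     windows=(w, 10_000_000))
            sets.append(set(s.selected_degs)
                        if s.selected_window == w else None)
        # direct subset check over growing windows
        prev = set()
        for w in scan.windows:
            one = distance_window_scan(enriched_pos, de,
                                       study.annotation.genes, rate,
                                       windows=(w, w + 1))
            degs = set(one.selected_degs)
            assert prev <= degs
            prev = degs

    def test_too_few_windows_fatal(self, study):
        de = de_test(study.expression)
        with pytest.raises(ValueError):
            distance_window_scan(study.cpg_positions, de,
                                 study.annotation.genes, 0.3,
                                 windows=(1000,))


def _wm(unit, snps, weights=None):
    w = weights if weights is not None else np.ones(len(snps))
    return WeightModel(unit, "1", 1000, pd.DataFrame({
        "snp_id": snps, "effect_allele": "A", "other_allele": "G",
        "weight": w}))


class TestEqtlOverlap:
    def test_full_overlap_with_small_null_is_extreme(self):
        meqtl = [_wm("cg1", [f"s{i}" for i in range(10)])]
        eqtl = [_wm("geneA", [f"s{i}" for i in range(10)])]
        # many genes with one overlapping SNP of 100 set the median null
        for j in range(8):
            eqtl.append(_wm(f"gene{j}", ["s0"] + [f"x{j}_{i}"
                                                  for i in range(99)]))
        table = eqtl_overlap_enrichment(meqtl, eqtl).set_index("gene_id")
        assert table.loc["geneA", "p0"] == pytest.approx(0.01)
        assert table.loc["geneA", "p"] < 1e-10

    def test_zero_overlap_p_one(self):
        meqtl = [_wm("cg1", ["a", "b"])]
        eqtl = [_wm("geneA", ["a", "b"]), _wm("geneB", ["q", "r"])]
        table = eqtl_overlap_enrichment(meqtl, eqtl).set_index("gene_id")
        assert table.loc["geneB", "k"] == 0
        assert table.loc["geneB", "p"] == pytest.approx(1.0)

    def test_identical_proportions_never_enriched(self):
        meqtl = [_wm("cg1", ["a"])]
        eqtl = [_wm(f"gene{j}", ["a"] + [f"x{j}_{i}" for i in range(9)])
                for j in range(5)]
        table = eqtl_overlap_enrichment(meqtl, eqtl)
        np.testing.assert_allclose(table["p0"], 0.1)
        assert (table["p"] >= 0.5).all()

    def test_no_gene_with_overlap_fatal(self):
        with pytest.raises(ValueError):
            eqtl_overlap_enrichment([_wm("cg1", ["a"])],
                                    [_wm("g1", ["z"])])


class TestMediation:
    def test_injected_interaction_recovered(self, study):
        mt = mediation_test(study.expression, study.methylation,
                            study.truth.mediation_pairs)
        assert (mt["p_interaction"] < 0.01).mean() >= 2 / 3

    def test_pure_main_effects_null_interaction(self):
        rng = np.random.default_rng(3)
        n = 120
        groups = ["tumour"] * 60 + ["NAT"] * 60
        tum = np.array([g == "tumour" for g in groups], float)
        meth_vals, expr_vals, pairs = [], [], []
        for i in range(40):
            m = 0.5 + 0.1 * rng.normal(size=n)
            y_log2 = 7 + 0.8 * tum + 1.5 * m + 0.3 * rng.normal(size=n)
            meth_vals.append(np.clip(m, 0, 1))
            expr_vals.append(np.rint(2.0 ** y_log2))
            pairs.append((f"g{i}", f"c{i}"))
        cols = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"sample_type": groups,
                             "age": np.linspace(40, 70, n)}, index=cols)
        meth = OmicsMatrix(pd.DataFrame(meth_vals,
                                        index=[f"c{i}" for i in range(40)],
                                        columns=cols), meta)
        expr = OmicsMatrix(pd.DataFrame(np.array(expr_vals, dtype=int),
                                        index=[f"g{i}" for i in range(40)],
                                        columns=cols), meta,
                           kind="expression")
        mt = mediation_test(expr, meth, pairs)
        ks = stats.kstest(mt["p_interaction"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_constant_methylation_gives_na(self, study):
        meth = study.methylation
        const = meth.values.copy()
        const.iloc[0, :] = 0.5
        m2 = OmicsMatrix(const, meth.metadata.copy())
        gene = study.truth.de_genes[0]
        cpg = const.index[0]
        mt = mediation_test(study.expression, m2, [(gene, cpg)])
        assert mt["p_interaction"].isna().all()

    def test_affine_rescaling_of_methylation_keeps_p(self, study):
        pairs = study.truth.mediation_pairs[:1]
        base = mediation_test(study.expression, study.methylation, pairs)
        scaled_vals = study.methylation.values * 3.0 + 0.1
        scaled = OmicsMatrix(scaled_vals, study.methylation.metadata.copy())
        again = mediation_test(study.expression, scaled, pairs)
        assert again.loc[0, "p_interaction"] == pytest.approx(
            base.loc[0, "p_interaction"], rel=1e-8)


class TestConcordance:
    def test_definitions_and_partition(self):
        dm = pd.DataFrame({"unit_id": ["c1", "c2", "c3"],
                           "direction": ["hypo", "hyper", "hypo"]})
        de = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                           "direction": ["up", "up", "down"]})
        pairs = [("c1", "g1"), ("c2", "g2"), ("c3", "g3"), ("c9", "g1")]
        out = direction_concordance(dm, de, pairs)
        assert out["negative"] == 1      # (hypo, up)
        assert out["positive"] == 2      # (hyper, up), (hypo, down)
        assert out["excluded"] == 1
        assert out["negative"] + out["positive"] == 3


class TestGeneSetFisher:
    def test_matches_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(30)]
        gene_set = universe[:6]
        pathways = {"self": universe[:6], "half": universe[3:15]}
        table = gene_set_fisher(gene_set, pathways,
                                universe).set_index("pathway")
        # one-sided Fisher == hypergeometric survival function
        p_oracle = stats.hypergeom.sf(5, 30, 6, 6)
        assert table.loc["self", "p"] == pytest.approx(p_oracle)

    def test_single_overlap_excluded(self):
        universe = [f"g{i}" for i in range(20)]
        table = gene_set_fisher(universe[:5], {"tiny": [universe[0],
                                                        universe[10]]},
                                universe)
        assert len(table) == 0

    def test_empty_database_fatal(self):
        with pytest.raises(ValueError):
            gene_set_fisher(["a"], {}, ["a"])
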