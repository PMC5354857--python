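"""Differential expression: fold change, Welch t, BH-FDR, filtering, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster.hierarchy import linkage

from lncnet.datatypes import InputError
from lncnet.de import (
    DEThresholds,
    average_linkage,
    bh_fdr,
    cluster_order,
    compute_fold_change,
    export_plot_tables,
    filter_significant,
    run_de,
    summarize_counts,
    welch_t_test,
    _correlation_distance,
)

from conftest import toy_matrix


def de_frame(fc, p, fdr, biotype="lncRNA"):
    fc = np.asarray(fc, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(fc))],
            "biotype": biotype,
            "mean_tumor": fc,
            "mean_normal": 1.0,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p_value": p,
            "fdr": fdr,
        }
    )


class TestFoldChange:
    def test_hand_values(self):
        m = toy_matrix(
            [[4, 4, 2, 2], [3, 3, 3, 3], [0.75, 0.75, 0, 0]],
            ["mRNA"] * 3,
            ["tumor", "tumor", "normal", "normal"],
        )
        zero_pc = compute_fold_change(m, DEThresholds(pseudocount=0.0))
        assert zero_pc["fc"].iloc[0] == pytest.approx(2.0)
        assert zero_pc["log2fc"].iloc[0] == pytest.approx(1.0)
        assert zero_pc["fc"].iloc[1] == pytest.approx(1.0)
        # pseudocount keeps a zero-expression denominator computable
        with_pc = compute_fold_change(m, DEThresholds(pseudocount=0.25))
        assert with_pc["fc"].iloc[2] == pytest.approx(4.0)
        assert with_pc["log2fc"].iloc[2] == pytest.approx(2.0)

    def test_identical_groups_fc_one_any_pseudocount(self):
        m = toy_matrix([[5, 7, 5, 7]], ["mRNA"], ["tumor", "tumor", "normal", "normal"])
        for pc in (0.0, 0.25, 1.0):
            out = compute_fold_change(m, DEThresholds(pseudocount=pc))
            assert out["fc"].iloc[0] == pytest.approx(1.0)
            assert out["log2fc"].iloc[0] == pytest.approx(0.0)


class TestWelch:
    def test_identical_samples_p_one(self):
        m = toy_matrix(
            [[1, 2, 3, 1, 2, 3]], ["mRNA"],
            ["tumor"] * 3 + ["normal"] * 3,
        )
        assert welch_t_test(m).iloc[0] == pytest.approx(1.0)

    def test_zero_variance_unequal_means_minimal_p(self):
        m = toy_matrix([[4, 4, 1, 1]], ["mRNA"], ["tumor", "tumor", "normal", "normal"])
        p = welch_t_test(m).iloc[0]
        assert 0 < p <= np.nextafter(0.0, 1.0) * 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_welch(self, seed):
        """Vectorized Welch p agrees with scipy's routine to 1e-10."""
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(2, 1, size=(20, 9))
        m = toy_matrix(vals, ["mRNA"] * 20, ["tumor"] * 5 + ["normal"] * 4)
        ours = welch_t_test(m, pseudocount=0.25)
        x = np.log2(vals[:, :5] + 0.25)
        y = np.log2(vals[:, 5:] + 0.25)
        ref = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(ours.values, ref, atol=1e-10)

    def test_single_sample_group_errors(self):
        m = toy_matrix([[1, 2, 3]], ["mRNA"], ["tumor", "tumor", "normal"])
        with pytest.raises(InputError):
            welch_t_test(m)


class TestBH:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.3] * 5), [0.3] * 5)
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_monotonicity(self, ps, rnd):
        p = np.array(ps)
        q = bh_fdr(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=100)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestFilter:
    def test_strict_boundaries(self):
        rec = filter_significant(
            de_frame([2.0, 3.0, 0.4], [0.001, 0.01, 0.04], [0.001, 0.05, 0.09])
        )
        assert not rec["significant"].iloc[0]  # fc exactly 2.0: strict >
        assert rec["direction"].iloc[0] == "none"
        assert rec["significant"].iloc[1] and rec["direction"].iloc[1] == "up"
        assert rec["significant"].iloc[2] and rec["direction"].iloc[2] == "down"

    def test_idempotent(self):
        rec = de_frame([5.0, 0.1], [0.01, 0.5], [0.01, 0.9])
        once = filter_significant(rec)
        twice = filter_significant(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSummaries:
    def test_totals_are_directional_sums(self):
        # the headline bookkeeping: 101 up + 738 down lncRNAs, 22/221 beyond FC 10
        fcs = (
            [20.0] * 22 + [3.0] * 79          # up: 22 extreme + 79 moderate
            + [0.05] * 221 + [0.3] * 517      # down: 221 extreme + 517 moderate
        )
        rec = de_frame(fcs, [0.01] * 839, [0.01] * 839)
        rec = filter_significant(rec)
        out = summarize_counts(rec, extra_fc_cut=10.0).set_index("biotype")
        row = out.loc["lncRNA"]
        assert row["n_up"] == 101 and row["n_down"] == 738
        assert row["n_total"] == row["n_up"] + row["n_down"] == 839
        assert row["n_up_extreme"] == 22 and row["n_down_extreme"] == 221
        assert row["n_extreme_total"] == 243

    def test_empty_records(self):
        rec = filter_significant(de_frame([1.0], [0.9], [0.9]))
        out = summarize_counts(rec)
        assert (out[["n_up", "n_down", "n_total"]].values == 0).all()


class TestPlotTables:
    def test_volcano_y_axis(self):
        rec = filter_significant(
            de_frame([5, 5, 5], [0.001] * 3, [1.0, 0.01, 0.0])
        )
        v = export_plot_tables(rec)["volcano"]
        assert v["neg_log10_fdr"].iloc[0] == pytest.approx(0.0)
        assert v["neg_log10_fdr"].iloc[1] == pytest.approx(2.0)
        assert v["neg_log10_fdr"].iloc[2] == 320.0  # documented cap for FDR 0
        assert v["class"].iloc[2] == "up"
        assert v["class"].iloc[0] == "ns"


class TestClustering:
    def test_identical_genes_adjacent(self):
        vals = [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]]
        m = toy_matrix(vals, ["mRNA"] * 3, ["tumor", "tumor", "normal", "normal"])
        rec = filter_significant(de_frame([5, 5, 5], [0.01] * 3, [0.01] * 3))
        order, _ = average_linkage(
            _correlation_distance(np.asarray(vals, float), ["g0", "g1", "g2"])
        )
        i0, i1 = order.index("g0"), order.index("g1")
        assert abs(i0 - i1) == 1  # r = 1 pair merges first
        assert order.index("g2") in (0, 2)
        gene_order, sample_order = cluster_order(m, rec, pseudocount=0.0)
        assert set(gene_order) == {"g0", "g1", "g2"}
        assert len(sample_order) == 4

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            data = rng.normal(size=(6, 8))
            ids = [f"g{i}" for i in range(6)]
            dist = _correlation_distance(data, ids)
            _, heights = average_linkage(dist)
            from scipy.spatial.distance import squareform

            ref = linkage(squareform(dist.values, checks=False), method="average")
            np.testing.assert_allclose(sorted(heights), sorted(ref[:, 2]), atol=1e-10)

    def test_constant_gene_maximal_distance(self):
        data = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        d = _correlation_distance(data, ["flat", "g"])
        assert d.loc["flat", "g"] == 2.0

    def test_requires_two_significant_genes(self):
        m = toy_matrix([[1, 2, 3, 4]], ["mRNA"], ["tumor", "tumor", "normal", "normal"])
        rec = filter_significant(de_frame([1.0], [0.9], [0.9]))
        with pytest.raises(InputError):
            cluster_order(m, rec)


class TestRecovery:
    def test_planted_de_recovered_single_cohort(self, matrix_truth):
        matrix, truth = matrix_truth
        rec = run_de(matrix)
        called = set(rec.loc[rec["significant"], "gene_id"])
        planted = set(truth.de_genes)
        assert len(called & planted) >= 18  # sensitivity >= 0.9 at |log2FC| = 4
        directions = dict(zip(rec["gene_id"], rec["direction"]))
        for g in called & planted:
            assert directions[g] == truth.de_genes[g][0]

    def test_fdr_computed_per_biotype_by_default(self, matrix_truth):
        matrix, _ = matrix_truth
        rec = run_de(matrix)
        for bt in ("mRNA", "lncRNA"):
            sub = rec[rec["biotype"] == bt]
            np.testing.assert_allclose(
                sub["fdr"].values, bh_fdr(sub["p_value"].values), atol=1e-12
            )
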