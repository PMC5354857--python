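"""Co-expression networks: correlations, thresholds, degrees, export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncnet.datatypes import InputError
from lncnet.network import (
    build_network,
    correlation_pvalue,
    export_graph,
    extract_subnetwork,
    node_degrees,
    pearson_correlation,
    read_graphml,
)
from lncnet.simulate import simulate_expression

from conftest import small_config, toy_matrix


def brute_force_network(matrix, lnc, mrna, min_abs_pcc, max_p, cohort="tumor"):
    """Independent oracle: per-pair scipy correlation, explicit thresholds."""
    samples = matrix.samples_in(cohort)
    l2 = matrix.log2()
    edges = set()
    for l, m in itertools.product(sorted(lnc), sorted(mrna)):
        r, p = stats.pearsonr(l2.loc[l, samples], l2.loc[m, samples])
        if abs(r) >= min_abs_pcc and p < max_p:
            edges.add((l, m))
    return edges


class TestPearson:
    def test_hand_values(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=12, unique=True),
        st.lists(st.floats(-100, 100), min_size=12, max_size=12, unique=True),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_and_affine_invariance(self, xs, ys, a, b):
        x = np.array(xs)
        y = np.array(ys)[: len(x)]
        if len(set(y.tolist())) < 2:
            return
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_correlation(a * x + b, y) == pytest.approx(r, abs=1e-9)


class TestCorrelationP:
    def test_limits(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)
        assert correlation_pvalue(1.0, 5) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_t_transform_value(self):
        # r = 0.8, n = 4: t = 1.8856 on 2 df
        assert correlation_pvalue(0.8, 4) == pytest.approx(0.2, abs=0.001)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_reference(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 11))
        r = pearson_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert correlation_pvalue(r, 11) == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(InputError):
            correlation_pvalue(0.5, 2)


class TestBuildNetwork:
    def test_zero_noise_star_module(self):
        edges = tuple((f"LNC0000", f"MRNA{j:04d}", 1.0) for j in range(5))
        cfg = small_config(seed=1, noise_sd=0.0, planted_edges=edges,
                           n_de_up_mrna=0, n_de_down_mrna=0,
                           n_de_up_lncrna=0, n_de_down_lncrna=0)
        matrix, _ = simulate_expression(cfg)
        net = build_network(
            matrix, ["LNC0000"], [f"MRNA{j:04d}" for j in range(5)],
            min_abs_pcc=0.99,
        )
        assert net.n_nodes == 6 and net.n_edges == 5
        assert net.graph.degree("LNC0000") == 5

    def test_unattainable_threshold_empty(self, matrix_truth):
        matrix, _ = matrix_truth
        net = build_network(matrix, ["LNC0000"], ["MRNA0000"], min_abs_pcc=1.01)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_matches_brute_force_oracle(self, matrix_truth):
        matrix, _ = matrix_truth
        lnc = [f"LNC{i:04d}" for i in range(10)]
        mrna = [f"MRNA{i:04d}" for i in range(10)]
        for cut, p in [(0.3, 1.0), (0.5, 0.05), (0.8, 0.001)]:
            net = build_network(matrix, lnc, mrna, min_abs_pcc=cut, max_p=p)
            got = {tuple(e[:2]) for e in net.edges_frame().itertuples(index=False)}
            assert got == brute_force_network(matrix, lnc, mrna, cut, p)

    def test_threshold_monotonicity_nested(self, matrix_truth):
        matrix, _ = matrix_truth
        lnc = [f"LNC{i:04d}" for i in range(20)]
        mrna = [f"MRNA{i:04d}" for i in range(20)]
        loose = build_network(matrix, lnc, mrna, min_abs_pcc=0.80)
        tight = build_network(matrix, lnc, mrna, min_abs_pcc=0.90)
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_bipartite_and_thresholds_recorded(self, matrix_truth):
        matrix, _ = matrix_truth
        net = build_network(
            matrix, [f"LNC{i:04d}" for i in range(30)],
            [f"MRNA{i:04d}" for i in range(30)], min_abs_pcc=0.5,
        )
        for u, v in net.graph.edges:
            kinds = {net.graph.nodes[u]["biotype"], net.graph.nodes[v]["biotype"]}
            assert kinds == {"lncRNA", "mRNA"}
        for _, _, d in net.graph.edges(data=True):
            assert abs(d["pcc"]) >= net.min_abs_pcc
            assert (d["sign"] == "positive") == (d["pcc"] > 0)

    def test_constant_gene_dropped_with_warning(self, caplog):
        vals = np.vstack([np.full(6, 3.0), np.arange(6), np.arange(6) * 2])
        m = toy_matrix(vals, ["lncRNA", "lncRNA", "mRNA"],
                       ["tumor"] * 4 + ["normal"] * 2)
        with caplog.at_level("WARNING"):
            net = build_network(m, ["g0", "g1"], ["g2"], min_abs_pcc=0.5,
                                cohort="all", log2=False)
        assert "constant" in caplog.text
        assert "g0" not in net.graph

    def test_empty_gene_set_and_small_cohort_error(self, matrix_truth):
        matrix, _ = matrix_truth
        with pytest.raises(InputError):
            build_network(matrix, [], ["MRNA0000"])
        tiny = toy_matrix([[1, 2, 3], [1, 2, 4]], ["lncRNA", "mRNA"],
                          ["tumor", "tumor", "normal"])
        with pytest.raises(InputError, match="< 3 samples"):
            build_network(tiny, ["g0"], ["g1"])


class TestDegrees:
    def path_network(self):
        vals = np.vstack([np.arange(8), np.arange(8) * 2, np.arange(8) * 3])
        m = toy_matrix(vals, ["lncRNA", "mRNA", "lncRNA"],
                       ["tumor"] * 6 + ["normal"] * 2,
                       gene_ids=["l1", "m1", "l2"])
        return build_network(m, ["l1", "l2"], ["m1"], min_abs_pcc=0.9, log2=False)

    def test_path_degrees(self):
        deg = node_degrees(self.path_network()).set_index("gene_id")["degree"]
        assert deg["m1"] == 2 and deg["l1"] == 1 and deg["l2"] == 1

    def test_handshake_and_recount(self, matrix_truth):
        matrix, _ = matrix_truth
        net = build_network(
            matrix, [f"LNC{i:04d}" for i in range(15)],
            [f"MRNA{i:04d}" for i in range(15)], min_abs_pcc=0.4,
        )
        deg = node_degrees(net)
        by_bt = deg.groupby("biotype")["degree"].sum()
        assert by_bt.get("lncRNA", 0) == by_bt.get("mRNA", 0) == net.n_edges
        # brute-force incidence recount
        counts = {}
        for l, m in net.graph.edges:
            counts[l] = counts.get(l, 0) + 1
            counts[m] = counts.get(m, 0) + 1
        for _, row in deg.iterrows():
            assert counts[row["gene_id"]] == row["degree"]

    def test_ranking_ties_lexicographic(self):
        deg = node_degrees(self.path_network())
        assert deg["gene_id"].tolist() == ["m1", "l1", "l2"]
        top = node_degrees(self.path_network(), top_k=1)
        assert top["gene_id"].tolist() == ["m1"]


class TestSubnetwork:
    def test_seed_with_three_partners(self):
        edges = tuple((f"LNC{i:04d}", "MRNA0000", 0.99) for i in range(3))
        cfg = small_config(seed=2, noise_sd=0.05, planted_edges=edges)
        matrix, _ = simulate_expression(cfg)
        sub, report = extract_subnetwork(
            matrix, [f"LNC{i:04d}" for i in range(10)], ["MRNA0000"],
        )
        assert sub.n_nodes == 4 and sub.n_edges == 3
        assert report.loc[0, "n_partners"] == 3

    def test_seed_without_partner_excluded(self, matrix_truth):
        matrix, _ = matrix_truth
        sub, report = extract_subnetwork(
            matrix, ["LNC0050"], ["MRNA0050"], min_abs_pcc=0.999, max_p=1.0,
        )
        assert "MRNA0050" not in sub.graph
        assert report.loc[0, "n_partners"] == 0

    def test_subnetwork_subset_of_full(self, matrix_truth):
        matrix, truth = matrix_truth
        lnc = [f"LNC{i:04d}" for i in range(20)]
        mrna = [f"MRNA{i:04d}" for i in range(20)]
        seeds = mrna[:5]
        full = build_network(matrix, lnc, mrna, min_abs_pcc=0.5, max_p=0.05)
        sub, _ = extract_subnetwork(matrix, lnc, seeds, min_abs_pcc=0.5, max_p=0.05)
        restricted = {
            e for e in full.graph.edges if e[0] in set(seeds) or e[1] in set(seeds)
        }
        assert {tuple(sorted(e)) for e in sub.graph.edges} == {
            tuple(sorted(e)) for e in restricted
        }

    def test_empty_seed_error(self, matrix_truth):
        matrix, _ = matrix_truth
        with pytest.raises(InputError):
            extract_subnetwork(matrix, ["LNC0000"], [])


class TestExport:
    def test_round_trip(self, tmp_path, matrix_truth):
        matrix, _ = matrix_truth
        net = build_network(
            matrix, [f"LNC{i:04d}" for i in range(10)],
            [f"MRNA{i:04d}" for i in range(10)], min_abs_pcc=0.5,
        )
        export_graph(net, tmp_path / "edges.tsv", tmp_path / "net.graphml")
        back = read_graphml(tmp_path / "net.graphml", net.min_abs_pcc, net.max_p)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }
        lines = (tmp_path / "edges.tsv").read_text().strip("\n").split("\n")
        assert len(lines) == net.n_edges + 1  # header + edges

    def test_empty_network_export(self, tmp_path, matrix_truth):
        matrix, _ = matrix_truth
        net = build_network(matrix, ["LNC0000"], ["MRNA0000"], min_abs_pcc=1.01)
        export_graph(net, tmp_path / "edges.tsv", tmp_path / "net.graphml")
        assert (tmp_path / "edges.tsv").read_text().strip("\n").count("\n") == 0
        assert nx.read_graphml(tmp_path / "net.graphml").number_of_nodes() == 0
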