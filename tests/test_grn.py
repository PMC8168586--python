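"""Capture imputation, network construction and subnetwork rules."""

import numpy as np
import pandas as pd
import pytest

from capseq.grn import (assign_degs_to_clusters, build_network,
                        cluster_subnetworks, degree_distribution,
                        impute_capture, recovered_true_edges)
from capseq.types import (AlignmentError, CapturePanel, DataError,
                          GeneNetwork, GRNParams)

from conftest import make_matrix


def test_impute_forced_arithmetic():
    """Pre library 100, post library 400, post count 8 -> imputed 2."""
    pre = make_matrix([[10], [90]], genes=["TF1", "other"], cells=["c"])
    post = make_matrix([[8], [392]], genes=["TF1", "other"], cells=["c"])
    out = impute_capture(pre, post, CapturePanel({"TF1"}))
    assert out.to_frame().loc["TF1", "c"] == pytest.approx(2.0)
    assert out.to_frame().loc["other", "c"] == 90


def test_impute_identity_when_post_equals_pre():
    pre = make_matrix([[4, 2], [6, 8]], genes=["TF1", "g"])
    out = impute_capture(pre, pre.copy(), CapturePanel({"TF1"}))
    assert np.allclose(out.to_frame().values, pre.to_frame().values)


def test_impute_new_panel_gene_appended():
    pre = make_matrix([[5, 5]], genes=["g"])
    post = make_matrix([[3, 3], [2, 4]], genes=["g", "TF9"])
    out = impute_capture(pre, post, CapturePanel({"TF9"}))
    assert out.genes == ["g", "TF9"]
    assert out.n_genes == pre.n_genes + 1
    # rescale: pre libs (5,5), post libs (5,7)
    assert out.to_frame().loc["TF9"].tolist() == pytest.approx(
        [2 * 5 / 5, 4 * 5 / 7])


def test_impute_cell_mismatch_rejected():
    pre = make_matrix([[1, 2]], genes=["g"], cells=["a", "b"])
    post = make_matrix([[1, 2]], genes=["g"], cells=["b", "a"])
    with pytest.raises(AlignmentError):
        impute_capture(pre, post, CapturePanel({"g"}))


def test_impute_zero_post_library_rejected():
    pre = make_matrix([[1]], genes=["g"])
    post = make_matrix([[0]], genes=["g"])
    with pytest.raises(DataError):
        impute_capture(pre, post, CapturePanel({"g"}))


def test_duplicated_gene_row_gives_unit_correlation():
    rng = np.random.default_rng(0)
    v = rng.normal(size=20)
    norm = pd.DataFrame([v, v, rng.normal(size=20)],
                        index=["a", "b", "c"],
                        columns=[f"c{i}" for i in range(20)])
    net = build_network(norm, GRNParams())
    assert net.has_edge("a", "b")
    assert net.graph.edges["a", "b"]["weight"] == pytest.approx(1.0)


def test_independent_noise_yields_no_edges():
    """50 independent N(0,1) genes at 100 cells: no |r| > 0.8 edges in at
    least 19 of 20 seeds."""
    clean = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        norm = pd.DataFrame(rng.normal(size=(50, 100)),
                            index=[f"g{i}" for i in range(50)],
                            columns=[f"c{i}" for i in range(100)])
        if build_network(norm).n_edges == 0:
            clean += 1
    assert clean >= 19


def test_four_gene_toy_edges_match_hand_correlations():
    base = np.array([0.0, 1, 2, 3, 4, 5, 6, 7])
    norm = pd.DataFrame(
        [base,
         base * 2 + 1,                       # r = 1 with g0
         -base + 10,                          # r = -1 with g0
         np.array([0.0, 5, 1, 4, 2, 3, 6, 0])],  # weak vs g0
        index=["g0", "g1", "g2", "g3"],
        columns=[f"c{i}" for i in range(8)])
    r_weak = np.corrcoef(norm.loc["g0"], norm.loc["g3"])[0, 1]
    assert abs(r_weak) < 0.8
    net = build_network(norm)
    expected = {frozenset(p) for p in
                [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]}
    assert net.edge_set() == expected
    assert net.graph.edges["g0", "g2"]["weight"] == pytest.approx(-1.0)


def test_zero_variance_genes_recorded_and_excluded():
    norm = pd.DataFrame([[1.0] * 10, np.arange(10.0)],
                        index=["flat", "var"],
                        columns=[f"c{i}" for i in range(10)])
    net = build_network(norm)
    assert "flat" not in net.nodes()
    assert net.graph.graph["dropped_zero_variance"] == ["flat"]


def test_network_invariant_to_gene_order():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(12, 40))
    vals[1] = vals[0] + rng.normal(0, 0.1, size=40)
    norm = pd.DataFrame(vals, index=[f"g{i}" for i in range(12)],
                        columns=[f"c{i}" for i in range(40)])
    net1 = build_network(norm)
    net2 = build_network(norm.iloc[::-1])
    assert net1.edge_set() == net2.edge_set()


def deg_row(gene, lnfc, fdr=0.01, pct=0.8):
    return {"gene": gene, "ln_fc": lnfc, "p": fdr, "fdr": fdr,
            "pct_in": pct, "pct_out": 0.1}


def test_multi_cluster_deg_assigned_to_highest_fold_change():
    tables = {
        "A_vs_rest": pd.DataFrame([deg_row("g", 1.2)]),
        "B_vs_rest": pd.DataFrame([deg_row("g", 0.7)]),
    }
    assignment = assign_degs_to_clusters(
        tables, {"A_vs_rest": "A", "B_vs_rest": "B"})
    assert assignment["g"] == "A"


def test_deg_pct_rule_excludes_low_fraction():
    tables = {"A_vs_rest": pd.DataFrame([deg_row("g", 1.0, pct=0.4)])}
    assignment = assign_degs_to_clusters(tables, {"A_vs_rest": "A"},
                                         GRNParams(deg_pct=0.5))
    assert "g" not in assignment.index


def _toy_net(edges, tfs=()):
    return GeneNetwork.from_edges([(a, b, 1.0) for a, b in edges],
                                  tf_genes=tfs)


def test_small_components_dropped():
    net = _toy_net([("a", "b"), ("c", "d"), ("d", "e"), ("c", "e")])
    tables = {"A_vs_rest": pd.DataFrame(
        [deg_row(g, 1.0) for g in "abcde"])}
    sub = cluster_subnetworks(net, tables, {"A_vs_rest": "A"}, set())
    assert set(sub.nodes()) == {"c", "d", "e"}  # 2-node component removed


def test_tf_neighbor_fraction_rule():
    """A TF with 1/4 neighbors in cluster DEGs (25% >= 20%) attaches; with
    1/6 neighbors (17% < 20%) it does not."""
    edges = [("tf1", f"d{i}") for i in range(4)]
    edges += [("tf2", f"e{i}") for i in range(6)]
    edges += [("d0", "d1"), ("e0", "d0")]
    net = _toy_net(edges, tfs={"tf1", "tf2"})
    degs = ["d0", "d1", "d2"] + ["e0"]
    tables = {"A_vs_rest": pd.DataFrame([deg_row(g, 1.0) for g in degs])}
    # tf1 neighbors d0..d3: 3/4 in DEGs; tf2 neighbors e0..e5: 1/6
    sub = cluster_subnetworks(net, tables, {"A_vs_rest": "A"},
                              {"tf1", "tf2"},
                              GRNParams(min_component=1))
    assert "tf1" in sub.nodes()
    assert "tf2" not in sub.nodes()
    # exactly 1/4 (25%) also attaches
    tables2 = {"A_vs_rest": pd.DataFrame([deg_row("d0", 1.0),
                                          deg_row("x", 1.0)])}
    sub2 = cluster_subnetworks(net, tables2, {"A_vs_rest": "A"},
                               {"tf1", "tf2"}, GRNParams(min_component=1))
    assert "tf1" in sub2.nodes()


def test_subnetwork_cluster_attribute_set():
    net = _toy_net([("a", "b"), ("b", "c")])
    tables = {"X_vs_rest": pd.DataFrame([deg_row(g, 1.0)
                                         for g in "abc"])}
    sub = cluster_subnetworks(net, tables, {"X_vs_rest": "X"}, set())
    assert all(sub.graph.nodes[n]["cluster"] == "X" for n in sub.nodes())


def test_degree_distribution_star():
    net = _toy_net([("hub", f"s{i}") for i in range(4)])
    deg, hist = degree_distribution(net)
    assert sorted(deg.tolist()) == [1, 1, 1, 1, 4]
    assert dict(zip(hist["degree"], hist["n_nodes"])) == {1: 4, 4: 1}


def test_degree_distribution_empty():
    deg, hist = degree_distribution(GeneNetwork())
    assert deg.empty and hist.empty


def test_degree_matches_adjacency_oracle():
    rng = np.random.default_rng(1)
    net = GeneNetwork()
    nodes = [f"n{i}" for i in range(12)]
    for _ in range(20):
        a, b = rng.choice(12, size=2, replace=False)
        if not net.has_edge(nodes[a], nodes[b]):
            net.add_edge(nodes[a], nodes[b])
    adj = np.zeros((12, 12))
    for a, b in net.graph.edges:
        i, j = nodes.index(a), nodes.index(b)
        adj[i, j] = adj[j, i] = 1
    deg, _ = degree_distribution(net)
    for i, n in enumerate(nodes):
        if n in deg.index:
            assert deg[n] == adj[i].sum()


def test_imputed_network_recovers_more_true_edges(default_run):
    truth = default_run["truth"]
    genes = sorted((set(truth.true_edges["tf"])
                    | set(truth.true_edges["target"])
                    | truth.panel.target_genes))
    net_imp = build_network(default_run["norm_imputed"], genes=genes)
    net_pre = build_network(default_run["norm_pre"], genes=genes)
    r_imp = recovered_true_edges(net_imp, truth.true_edges)
    r_pre = recovered_true_edges(net_pre, truth.true_edges)
    assert r_imp >= max(1.3 * r_pre, 5)
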