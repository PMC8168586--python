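"""Network enrichment, Fisher/hypergeometric statistics, evidence filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from capseq.net_enrich import (degree_preserving_permutation,
                               fisher_target_enrichment, filter_tf_targets,
                               incident_edge_count, nea,
                               paired_term_comparison, tfppi_enrichment)
from capseq.types import DataError, FormatError, GeneNetwork

from test_stats import signed_rank_oracle

TOY_EDGES = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"),
             ("f", "a"), ("a", "c")]


def toy_net():
    return GeneNetwork.from_edges([(u, v, 1.0) for u, v in TOY_EDGES])


def degree_sequence(edges, nodes):
    deg = {n: 0 for n in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return tuple(deg[n] for n in nodes)


def enumerate_degree_graphs(nodes, degree_seq, n_edges):
    """All simple labeled graphs on ``nodes`` with the given degree
    sequence (brute force over edge subsets)."""
    possible = list(itertools.combinations(nodes, 2))
    out = []
    for subset in itertools.combinations(possible, n_edges):
        if degree_sequence(subset, nodes) == degree_seq:
            out.append(subset)
    return out


def test_every_permutation_preserves_degree_sequence():
    nodes = sorted({n for e in TOY_EDGES for n in e})
    target = degree_sequence(TOY_EDGES, nodes)
    rng = np.random.default_rng(0)
    for _ in range(300):
        perm = degree_preserving_permutation(TOY_EDGES, rng)
        assert degree_sequence(perm, nodes) == target
        assert len({frozenset(e) for e in perm}) == len(TOY_EDGES)
        assert all(a != b for a, b in perm)


def test_nea_empirical_p_matches_exhaustive_enumeration():
    """Empirical p on the 6-node toy is within 3 Monte-Carlo SEs of the
    exact value under uniform sampling of degree-preserving graphs."""
    nodes = sorted({n for e in TOY_EDGES for n in e})
    target = degree_sequence(TOY_EDGES, nodes)
    graphs = enumerate_degree_graphs(nodes, target, len(TOY_EDGES))
    gene_set = {"a", "b"}
    net = toy_net()
    observed = incident_edge_count(net, gene_set)
    stats = [sum(1 for u, v in g if u in gene_set or v in gene_set)
             for g in graphs]
    p_exact = np.mean(np.asarray(stats) >= observed)
    n_perm = 10_000
    res = nea(net, gene_set, n_perm=n_perm, seed=1)
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(res.p - p_exact) <= 3 * se + 2 / n_perm


def test_nea_saturation_all_nodes():
    net = toy_net()
    res = nea(net, set(net.nodes()), n_perm=200, seed=0)
    assert res.observed == net.n_edges
    assert res.p == 1.0
    assert res.z is None  # degenerate null


def test_nea_deterministic_under_seed():
    net = toy_net()
    r1 = nea(net, {"a", "d"}, n_perm=500, seed=7)
    r2 = nea(net, {"a", "d"}, n_perm=500, seed=7)
    assert (r1.observed, r1.null_mean, r1.p) == (r2.observed, r2.null_mean,
                                                 r2.p)


def test_nea_disjoint_gene_set_rejected():
    with pytest.raises(DataError):
        nea(toy_net(), {"zz"}, n_perm=100, seed=0)


def test_nea_random_sets_z_centered():
    """z over randomly drawn gene sets averages near zero."""
    rng = np.random.default_rng(3)
    net = GeneNetwork()
    nodes = [f"n{i}" for i in range(30)]
    while net.n_edges < 60:
        a, b = rng.choice(30, size=2, replace=False)
        net.add_edge(nodes[a], nodes[b])
    zs = []
    for i in range(50):
        gs = set(rng.choice(nodes, size=6, replace=False))
        res = nea(net, gs, n_perm=150, seed=i)
        if res.z is not None:
            zs.append(res.z)
    assert abs(np.mean(zs)) < 0.3


def test_fisher_symmetric_table():
    odds, p, _ = fisher_target_enrichment(
        {f"n{i}" for i in range(10)} | {f"t{i}" for i in range(10)},
        {f"t{i}" for i in range(10)} | {f"u{i}" for i in range(10)},
        {f"{c}{i}" for c in "ntuo" for i in range(10)})
    assert odds == pytest.approx(1.0)
    assert p == 1.0


def test_fisher_example_two_sided():
    import scipy.stats
    odds, p = scipy.stats.fisher_exact([[8, 2], [2, 8]])
    # same table through the two-set interface
    universe = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(10)}
    net_nodes = {f"a{i}" for i in range(10)}
    targets = {f"a{i}" for i in range(8)} | {f"b{i}" for i in range(2)}
    odds2, p2, tab = fisher_target_enrichment(
        net_nodes, targets, universe,
        other_nodes={f"b{i}" for i in range(10)})
    assert tab.values.tolist() == [[8, 2], [2, 8]]
    assert p2 == pytest.approx(p) and p2 == pytest.approx(0.023, abs=0.001)


def test_fisher_zero_margin():
    _, p, _ = fisher_target_enrichment({"a"}, set(), {"a", "b"})
    assert p == 1.0


def test_tfppi_matches_cluster_typing_on_same_inputs():
    """Hypergeometric term enrichment agrees with the cell-typing scorer on
    identical inputs (cross-oracle equality)."""
    from capseq.cell_typing import MarkerTable, score_cluster_types

    universe = {f"g{i}" for i in range(20)}
    gmt = {"term1": {f"g{i}" for i in range(6)},
           "term2": {f"g{i}" for i in range(4, 12)}}
    subnet = {"c1": {f"g{i}" for i in range(3, 9)}}
    tab = tfppi_enrichment(subnet, gmt, universe)
    mt = MarkerTable({"term1": gmt["term1"]})
    typing = score_cluster_types({"c1": subnet["c1"]}, mt, universe)
    p_tfppi = tab.set_index("term").loc["term1", "p"]
    assert p_tfppi == pytest.approx(typing["p"].iloc[0], abs=1e-12)


def test_tfppi_disjoint_term_p_one_and_skip_recorded():
    universe = {"a", "b", "c", "d"}
    tab = tfppi_enrichment({"c1": {"a", "b"}},
                           {"hit": {"c", "d"}, "outside": {"zz"}}, universe)
    assert tab.set_index("term").loc["hit", "p"] == 1.0
    assert tab.attrs["skipped_terms"] == ["outside"]


def test_tfppi_degenerate_all_universe():
    universe = {"a", "b"}
    tab = tfppi_enrichment({"c": universe}, {"t": universe}, universe)
    assert tab["p"].iloc[0] == pytest.approx(1.0)


def test_paired_comparison_all_zero():
    _, p = paired_term_comparison([3, 4, 5], [3, 4, 5])
    assert p == 1.0


def test_paired_comparison_all_positive_n5():
    _, p = paired_term_comparison([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
    assert p == pytest.approx(2 / 2 ** 5)


def test_paired_comparison_negation_symmetry():
    pre = [5, 1, 7, 2, 9, 4]
    post = [6, 0, 9, 5, 3, 4]
    _, p1 = paired_term_comparison(pre, post)
    _, p2 = paired_term_comparison(post, pre)
    assert p1 == pytest.approx(p2)
    d = np.array(post, float) - np.array(pre, float)
    assert p1 == pytest.approx(signed_rank_oracle(d))


def test_filter_targets_weight_boundary_inclusive():
    wt = pd.DataFrame({"tf": ["t1", "t2"], "target": ["a", "b"],
                       "weight": [0.1, 0.0999]})
    links = filter_tf_targets(weight_table=wt)
    assert links == {("t1", "a")}


def test_filter_targets_p_boundary_strict():
    pt = pd.DataFrame({"tf": ["t1", "t2"], "target": ["a", "b"],
                       "p": [1e-7, 0.9e-7]})
    links = filter_tf_targets(p_table=pt)
    assert links == {("t2", "b")}


def test_filter_targets_union_deduplicates():
    wt = pd.DataFrame({"tf": ["t"], "target": ["a"], "weight": [0.5]})
    pt = pd.DataFrame({"tf": ["t"], "target": ["a"], "p": [1e-9]})
    assert filter_tf_targets(wt, pt) == {("t", "a")}


def test_filter_targets_malformed_rejected():
    with pytest.raises(FormatError):
        filter_tf_targets(weight_table=pd.DataFrame({"tf": ["t"]}))
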