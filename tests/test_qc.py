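"""Cell/gene filters and capture metrics against hand-enumerated toys."""

import numpy as np
import pytest

from capseq.qc import (capture_summary, cell_qc_table, filter_cells,
                       filter_genes, genewise_enrichment, on_target_fraction)
from capseq.types import (AlignmentError, CapturePanel, CountMatrix,
                          DataError, QCThresholds)

from conftest import make_matrix


def toy_qc_matrix():
    """Six cells, one QC violation each for A-D, E/F clean.

    300 endogenous genes + 2 spikes; thresholds: >=260 detected genes,
    library >= 500, top-200 fraction <= 0.9, spike fraction <= 0.14.
    """
    n_endo = 300
    genes = [f"g{i}" for i in range(n_endo)] + ["ERCC-1", "ERCC-2"]
    cells = list("ABCDEF")
    m = np.zeros((n_endo + 2, 6))
    m[:250, 0] = 3          # A: 250 genes < 260 (library 750 ok)
    m[:n_endo, 1] = 1       # B: library 300 < 500
    m[:n_endo, 2] = 1       # C: one dominant gene -> top-200 share 0.917
    m[0, 2] = 900
    m[:n_endo, 3] = 2       # D: spikes at 150/750 = 0.2 > 0.14
    m[n_endo, 3] = 150
    m[:n_endo, 4] = 2       # E, F: clean
    m[:n_endo, 5] = 2
    panel = CapturePanel({"g0", "g1"}, {"ERCC-1", "ERCC-2"}, {"ERCC-1"})
    th = QCThresholds(min_genes_per_cell=260, min_library_size=500,
                      max_top200_fraction=0.9, max_spike_fraction=0.14)
    return CountMatrix(genes, cells, m), panel, th


def test_toy_cells_exact_rule_enumeration():
    cm, panel, th = toy_qc_matrix()
    filtered, tab = filter_cells(cm, panel, th)
    assert filtered.cells == ["E", "F"]
    assert tab.loc["A", ~tab.loc["A"].index.str.startswith("pass")].tolist()
    assert not tab.loc["A", "pass_n_genes"]
    assert tab.loc["A", ["pass_library", "pass_complexity",
                         "pass_spike"]].all()
    assert not tab.loc["B", "pass_library"]
    assert tab.loc["B", ["pass_n_genes", "pass_complexity",
                         "pass_spike"]].all()
    assert not tab.loc["C", "pass_complexity"]
    assert tab.loc["C", ["pass_n_genes", "pass_library", "pass_spike"]].all()
    assert not tab.loc["D", "pass_spike"]
    assert tab.loc["D", ["pass_n_genes", "pass_library",
                         "pass_complexity"]].all()
    assert tab.loc[["E", "F"], "pass_all"].all()


def test_cell_just_below_gene_threshold_removed():
    """A cell expressing one gene fewer than the threshold is removed even
    when every other rule passes."""
    cm, panel, th = toy_qc_matrix()
    tab = cell_qc_table(cm, panel, th)
    assert tab.loc["A", "n_genes"] == th.min_genes_per_cell - 10
    # boundary: exactly at the threshold passes, one below fails
    m = cm.counts.toarray()
    m[250:260, 0] = 3  # bring A to exactly 260 genes
    tab2 = cell_qc_table(CountMatrix(cm.genes, cm.cells, m), panel, th)
    assert tab2.loc["A", "pass_n_genes"]
    m[259, 0] = 0      # 259 genes -> fails
    tab3 = cell_qc_table(CountMatrix(cm.genes, cm.cells, m), panel, th)
    assert not tab3.loc["A", "pass_n_genes"]


def test_all_passing_identity():
    cm, panel, th = toy_qc_matrix()
    sub = cm.subset_cells(["E", "F"])
    filtered, _ = filter_cells(sub, panel, th)
    assert filtered.cells == sub.cells
    assert (filtered.counts != sub.counts).nnz == 0


def test_no_cells_passing_is_an_error():
    cm, panel, th = toy_qc_matrix()
    sub = cm.subset_cells(["A", "B"])
    with pytest.raises(DataError, match="no cells passed"):
        filter_cells(sub, panel, th)


def test_filters_idempotent():
    cm, panel, th = toy_qc_matrix()
    once, _ = filter_cells(cm, panel, th)
    twice, _ = filter_cells(once, panel, th)
    assert twice.cells == once.cells
    g_once = filter_genes(once, th)
    g_twice = filter_genes(g_once, th)
    assert g_twice.genes == g_once.genes


def test_gene_mean_filter_is_strict():
    """A gene with mean count exactly 1.0 is removed (strict >)."""
    cm = make_matrix(np.array([[1] * 10, [2] * 10, [0] * 10]))
    out = filter_genes(cm, QCThresholds())
    assert out.genes == ["g1"]


def test_gene_filter_all_zero_matrix():
    cm = make_matrix(np.zeros((4, 3)))
    assert filter_genes(cm, QCThresholds()).genes == []


def test_gene_filter_matches_hand_means():
    vals = np.array([[0, 1, 2, 9],    # mean 3    -> keep
                     [1, 1, 1, 1],    # mean 1    -> drop (strict)
                     [0, 0, 5, 0],    # mean 1.25 -> keep
                     [0, 0, 0, 1],    # mean 0.25 -> drop
                     [2, 2, 2, 2]])   # mean 2    -> keep
    out = filter_genes(make_matrix(vals), QCThresholds())
    assert out.genes == ["g0", "g2", "g4"]


def test_on_target_fraction_arithmetic():
    cm = make_matrix([[3], [7]], genes=["panelA", "otherB"], cells=["c"])
    frac, med = on_target_fraction(cm, CapturePanel({"panelA"}))
    assert frac["c"] == pytest.approx(0.3)
    assert med == pytest.approx(0.3)


def test_on_target_fraction_all_panel_is_one():
    cm = make_matrix([[3, 1], [7, 2]])
    frac, _ = on_target_fraction(cm, CapturePanel({"g0", "g1"}))
    assert np.allclose(frac.values, 1.0)


def test_on_target_fraction_zero_library_missing():
    cm = make_matrix([[3, 0], [7, 0]])
    frac, _ = on_target_fraction(cm, CapturePanel({"g0"}))
    assert np.isnan(frac["c1"]) and frac["c0"] == pytest.approx(0.3)


def test_enrichment_identity_when_post_equals_pre(small_matrix):
    enr = genewise_enrichment(small_matrix, small_matrix.copy())
    assert np.allclose(enr.values, 0.0)


def test_enrichment_forced_arithmetic():
    """Mean pre CPM 3 and post CPM 127 give log2(128/4) = 5."""
    total = 1_000_000
    pre = make_matrix([[3, 3], [total - 3, total - 3]])
    post = make_matrix([[127, 127], [total - 127, total - 127]])
    enr = genewise_enrichment(pre, post)
    assert enr["g0"] == pytest.approx(5.0, abs=1e-6)


def test_enrichment_invariant_to_uniform_depth_scaling(small_matrix):
    post = make_matrix(small_matrix.counts.toarray() * 7,
                       genes=small_matrix.genes, cells=small_matrix.cells)
    enr = genewise_enrichment(small_matrix, post)
    assert np.allclose(enr.values, 0.0, atol=1e-12)


def test_enrichment_cell_mismatch_rejected(small_matrix):
    other = make_matrix(np.ones((3, 3)), genes=small_matrix.genes)
    with pytest.raises(AlignmentError):
        genewise_enrichment(small_matrix, other)


def test_capture_summary_identity():
    cm = make_matrix([[5, 1], [2, 8], [1, 1]])
    rep = capture_summary(cm, cm.copy(), CapturePanel({"g0", "g1"}))
    assert np.allclose(rep.detected_fold_change.dropna().values, 1.0)
    assert rep.mean_expression_r == pytest.approx(1.0)
    assert rep.n_expressed_panel_pre == rep.n_expressed_panel_post == 2


def test_capture_summary_hand_toy():
    pre = make_matrix([[2, 0], [8, 10]])
    post = make_matrix([[40, 10], [60, 90]])
    rep = capture_summary(pre, post, CapturePanel({"g0"}))
    assert rep.on_target_pre.tolist() == pytest.approx([0.2, 0.0])
    assert rep.on_target_post.tolist() == pytest.approx([0.4, 0.1])
    assert rep.detected_panel_pre.tolist() == [1, 0]
    assert rep.detected_panel_post.tolist() == [1, 1]
    assert rep.n_expressed_panel_pre == 1
    assert rep.n_expressed_panel_post == 1
    # mean CPM of g0: pre (200000 + 0)/2 = 1e5; post (4e5 + 1e5)/2 = 2.5e5
    assert rep.log2_enrichment["g0"] == pytest.approx(
        np.log2(250001.0 / 100001.0))


def test_simulated_on_target_matches_closed_form(default_sim):
    from capseq.simulate import expected_on_target_fraction

    pre, post, truth = default_sim
    f_post, _ = on_target_fraction(post, truth.panel)
    expected = expected_on_target_fraction(truth).mean()
    assert f_post.mean() == pytest.approx(expected, abs=0.02)


def test_detected_fold_change_exceeds_one_with_capture(default_sim):
    pre, post, truth = default_sim
    rep = capture_summary(pre, post, truth.panel)
    assert rep.detected_fold_change.dropna().median() > 1
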