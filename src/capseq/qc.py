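"""Cell/gene quality control and capture-performance metrics.

Cell filters are evaluated on the pre-capture matrix (four rules: detected
genes, library size, top-200 complexity, spike-in fraction) and the
surviving cell set is then applied to the post-capture matrix.  Capture
performance is summarised by per-cell on-target fractions, detected panel
genes per cell, the per-gene log2 CPM enrichment and the pre/post
mean-expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .types import (AlignmentError, CapturePanel, CountMatrix, DataError,
                    QCThresholds, align_check)


@dataclass
class CaptureReport:
    """Capture-performance summary for a matched pre/post pair."""

    on_target_pre: pd.Series
    on_target_post: pd.Series
    detected_panel_pre: pd.Series
    detected_panel_post: pd.Series
    log2_enrichment: pd.Series
    n_expressed_panel_pre: int
    n_expressed_panel_post: int
    mean_expression_r: float

    @property
    def median_on_target_pre(self) -> float:
        return float(self.on_target_pre.median())

    @property
    def median_on_target_post(self) -> float:
        return float(self.on_target_post.median())

    @property
    def detected_fold_change(self) -> pd.Series:
        """Per-cell post/pre ratio of detected panel genes (NaN when pre = 0)."""
        pre = self.detected_panel_pre.replace(0, np.nan)
        return self.detected_panel_post / pre

    def summary(self) -> dict:
        return {
            "median_on_target_pre": self.median_on_target_pre,
            "median_on_target_post": self.median_on_target_post,
            "median_detected_panel_pre": float(self.detected_panel_pre.median()),
            "median_detected_panel_post": float(self.detected_panel_post.median()),
            "median_detected_fold_change": float(
                self.detected_fold_change.median()),
            "n_expressed_panel_pre": self.n_expressed_panel_pre,
            "n_expressed_panel_post": self.n_expressed_panel_post,
            "median_panel_log2_enrichment": float(
                self.log2_enrichment.median()),
            "mean_expression_r": self.mean_expression_r,
        }


def _top_fraction(col: np.ndarray, top_n: int = 200) -> float:
    """Share of a cell's counts in its ``top_n`` most expressed genes
    (ties broken by gene order; 1.0 for cells with <= top_n genes)."""
    total = col.sum()
    if total == 0:
        return 1.0
    if col.size <= top_n:
        return 1.0
    # stable sort keeps gene order among ties
    order = np.argsort(-col, kind="stable")
    return float(col[order[:top_n]].sum() / total)


def cell_qc_table(counts: CountMatrix, panel: CapturePanel,
                  th: QCThresholds) -> pd.DataFrame:
    """Evaluate the four cell rules; one row per cell with values and flags."""
    spikes = sorted(panel.spike_ids & set(counts.genes))
    endo = [g for g in counts.genes if g not in panel.spike_ids]
    dense = counts.counts.toarray()
    lib = dense.sum(axis=0)
    spike_idx = [counts.gene_index()[g] for g in spikes]
    spike_sum = dense[spike_idx, :].sum(axis=0) if spike_idx else np.zeros_like(lib)
    endo_idx = [counts.gene_index()[g] for g in endo]
    n_genes = (dense[endo_idx, :] > 0).sum(axis=0)
    top200 = np.array([_top_fraction(dense[:, i]) for i in range(dense.shape[1])])
    with np.errstate(divide="ignore", invalid="ignore"):
        spike_frac = np.where(lib > 0, spike_sum / np.maximum(lib, 1), 1.0)
    tab = pd.DataFrame({
        "n_genes": n_genes,
        "library_size": lib,
        "top200_fraction": top200,
        "spike_fraction": spike_frac,
    }, index=counts.cells)
    tab["pass_n_genes"] = tab["n_genes"] >= th.min_genes_per_cell
    tab["pass_library"] = tab["library_size"] >= th.min_library_size
    tab["pass_complexity"] = tab["top200_fraction"] <= th.max_top200_fraction
    tab["pass_spike"] = tab["spike_fraction"] <= th.max_spike_fraction
    tab["pass_all"] = (tab["pass_n_genes"] & tab["pass_library"]
                       & tab["pass_complexity"] & tab["pass_spike"])
    return tab


def filter_cells(counts: CountMatrix, panel: CapturePanel, th: QCThresholds
                 ) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells failing any of the four quality rules.

    Rules (evaluated on this, i.e. the pre-capture, matrix): fewer than
    ``min_genes_per_cell`` detected non-spike genes; library smaller than
    ``min_library_size``; top-200 genes holding more than
    ``max_top200_fraction`` of counts; spike-ins exceeding
    ``max_spike_fraction`` of counts.
    """
    tab = cell_qc_table(counts, panel, th)
    keep = tab.index[tab["pass_all"]].tolist()
    if not keep:
        raise DataError("no cells passed quality control")
    return counts.subset_cells(keep), tab


def filter_genes(counts: CountMatrix, th: QCThresholds) -> CountMatrix:
    """Retain genes with mean count over cells strictly above
    ``min_gene_mean_count`` (order preserved)."""
    means = np.asarray(counts.counts.mean(axis=1)).ravel()
    keep = [g for g, m in zip(counts.genes, means)
            if m > th.min_gene_mean_count]
    return counts.subset_genes(keep)


def on_target_fraction(counts: CountMatrix, panel: CapturePanel
                       ) -> tuple[pd.Series, float]:
    """Per-cell fraction of counts on panel genes (spike-ins excluded from
    the numerator), plus the median over cells with non-zero libraries."""
    if counts.n_cells == 0:
        raise DataError("matrix has no cells")
    target = sorted(panel.target_genes & set(counts.genes))
    num = np.asarray(counts._rows(target).sum(axis=0)).ravel()
    lib = counts.library_sizes().values.astype(float)
    frac = np.where(lib > 0, num / np.maximum(lib, 1e-300), np.nan)
    series = pd.Series(frac, index=counts.cells, name="on_target_fraction")
    return series, float(series.median(skipna=True))


def _mean_cpm(counts: CountMatrix) -> pd.Series:
    """Mean CPM per gene; cells with empty libraries are excluded."""
    lib = counts.library_sizes().values.astype(float)
    ok = lib > 0
    if not ok.any():
        raise DataError("all libraries are empty")
    cpm = counts.counts[:, np.where(ok)[0]].multiply(1e6 / lib[ok]).toarray()
    return pd.Series(cpm.mean(axis=1), index=counts.genes)


def genewise_enrichment(pre: CountMatrix, post: CountMatrix) -> pd.Series:
    """Per-gene log2((mean post CPM + 1) / (mean pre CPM + 1))."""
    align_check(pre, post)
    pre_cpm = _mean_cpm(pre)
    post_cpm = _mean_cpm(post)
    return pd.Series(np.log2(post_cpm + 1) - np.log2(pre_cpm + 1),
                     index=pre.genes, name="log2_enrichment")


def capture_summary(pre: CountMatrix, post: CountMatrix, panel: CapturePanel
                    ) -> CaptureReport:
    """Fill a :class:`CaptureReport` for a matched pre/post pair.

    "Expressed" panel genes are those with non-zero mean counts; the
    mean-expression correlation is the Pearson r between log2(mean CPM + 1)
    of panel genes with non-zero mean in either matrix.
    """
    align_check(pre, post)
    target = sorted(panel.target_genes & set(pre.genes))
    on_pre, _ = on_target_fraction(pre, panel)
    on_post, _ = on_target_fraction(post, panel)
    det_pre = pre.detected_genes_per_cell(target)
    det_post = post.detected_genes_per_cell(target)
    pre_cpm = _mean_cpm(pre).loc[target]
    post_cpm = _mean_cpm(post).loc[target]
    pre_mean = pre.to_frame().loc[target].mean(axis=1)
    post_mean = post.to_frame().loc[target].mean(axis=1)
    expressed_either = (pre_mean > 0) | (post_mean > 0)
    if expressed_either.sum() >= 2:
        r = float(scipy.stats.pearsonr(
            np.log2(pre_cpm[expressed_either] + 1),
            np.log2(post_cpm[expressed_either] + 1)).statistic)
    else:
        r = float("nan")
    enrich = genewise_enrichment(pre, post).loc[target]
    return CaptureReport(
        on_target_pre=on_pre, on_target_post=on_post,
        detected_panel_pre=det_pre, detected_panel_post=det_post,
        log2_enrichment=enrich,
        n_expressed_panel_pre=int((pre_mean > 0).sum()),
        n_expressed_panel_post=int((post_mean > 0).sum()),
        mean_expression_r=r)


def qc_pipeline(pre: CountMatrix, post: CountMatrix, panel: CapturePanel,
                th: QCThresholds
                ) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Filter cells on pre, apply the surviving set to post, then filter
    genes of the pre matrix; post keeps its full gene universe so capture
    imputation can re-introduce panel genes."""
    pre_f, tab = filter_cells(pre, panel, th)
    post_f = post.subset_cells(pre_f.cells)
    pre_fg = filter_genes(pre_f, th)
    if pre_fg.n_genes == 0:
        raise DataError("no genes passed the mean-count filter")
    return pre_fg, post_f, tab
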