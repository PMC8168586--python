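"""Coexpression networks, post-capture imputation and cluster subnetworks.

The imputed matrix extends the pre-capture transcriptome by replacing panel
gene rows with post-capture values rescaled per cell by the pre/post
library-size ratio (replacement, not averaging: post-capture is strictly
more sensitive for panel genes).  Networks connect gene pairs whose Pearson
correlation on log-normalized values exceeds the |r| threshold and whose
BH-adjusted correlation p-value passes ``sig_alpha``; edge weights are the
signed correlations.  Cluster subnetworks follow the up-regulated-DEG,
highest-fold-change assignment, TF-neighbor and minimum-component rules.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from ._stats import bh_fdr
from .types import (AlignmentError, CapturePanel, CountMatrix, DataError,
                    GeneNetwork, GRNParams)


def impute_capture(pre: CountMatrix, post: CountMatrix, panel: CapturePanel
                   ) -> CountMatrix:
    """Extend the pre-capture matrix by rescaled post-capture panel rows.

    For each cell ``c`` and each panel gene expressed in post, the value is
    ``post_count(g, c) * pre_library(c) / post_library(c)``; non-panel rows
    are unchanged; panel genes absent from pre but expressed post appear as
    new rows appended in post order.
    """
    if pre.cells != post.cells:
        raise AlignmentError("pre and post must share the same ordered cells")
    pre_lib = pre.library_sizes().values.astype(float)
    post_lib = post.library_sizes().values.astype(float)
    if (post_lib == 0).any():
        raise DataError("post-capture cell(s) with zero library size")
    scale = pre_lib / post_lib
    post_dense = post.counts.toarray().astype(float)
    post_index = {g: i for i, g in enumerate(post.genes)}
    expressed_panel = [g for g in post.genes
                       if g in panel.target_genes
                       and post_dense[post_index[g]].sum() > 0]
    out_genes = list(pre.genes) + [g for g in expressed_panel
                                   if g not in set(pre.genes)]
    dense = np.zeros((len(out_genes), pre.n_cells))
    pre_dense = pre.counts.toarray().astype(float)
    gene_pos = {g: i for i, g in enumerate(out_genes)}
    dense[: pre.n_genes, :] = pre_dense
    for g in expressed_panel:
        dense[gene_pos[g], :] = post_dense[post_index[g], :] * scale
    gene_meta = pd.DataFrame(
        {"is_panel": [g in panel.target_genes or g in panel.spike_on_panel
                      for g in out_genes],
         "is_spike": [g in panel.spike_ids for g in out_genes],
         "imputed": [g in set(expressed_panel) for g in out_genes]},
        index=pd.Index(out_genes, name="gene"))
    return CountMatrix(out_genes, pre.cells, sp.csr_matrix(dense),
                       cell_meta=pre.cell_meta.drop(columns="library_size",
                                                    errors="ignore"),
                       gene_meta=gene_meta)


def correlation_with_p(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of rows plus two-sided p-values
    (t-distribution on n-2 degrees of freedom)."""
    n = values.shape[1]
    if n < 3:
        raise DataError("need at least three cells for correlations")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 1.0)
    return r, p


def build_network(norm: pd.DataFrame, params: GRNParams | None = None,
                  genes: list | None = None,
                  tf_genes: set | None = None) -> GeneNetwork:
    """Coexpression network: edge iff |Pearson r| > ``corr_threshold`` and
    BH-adjusted correlation p <= ``sig_alpha`` (on log-normalized values).

    Zero-variance genes are excluded and recorded on the returned network's
    ``graph.graph["dropped_zero_variance"]`` attribute.
    """
    params = params or GRNParams()
    sub = norm if genes is None else norm.loc[[g for g in genes
                                               if g in norm.index]]
    sd = sub.values.std(axis=1)
    dropped = [g for g, s in zip(sub.index, sd) if s == 0]
    sub = sub.loc[sd > 0]
    net = GeneNetwork()
    net.graph.graph["dropped_zero_variance"] = dropped
    tf_genes = tf_genes or set()
    for g in sub.index:
        net.add_node(g, is_tf=g in tf_genes)
    if sub.shape[0] < 2:
        return net
    r, p = correlation_with_p(sub.values)
    iu = np.triu_indices(sub.shape[0], k=1)
    q = bh_fdr(p[iu])
    mask = (np.abs(r[iu]) > params.corr_threshold) & (q <= params.sig_alpha)
    names = sub.index.to_numpy()
    for a, b, w in zip(names[iu[0][mask]], names[iu[1][mask]],
                       r[iu][mask]):
        net.add_edge(a, b, float(w))
        for n in (a, b):
            net.graph.nodes[n].setdefault("is_tf", n in tf_genes)
    return net


def assign_degs_to_clusters(deg_tables: dict, comparison_cluster: dict,
                            params: GRNParams | None = None
                            ) -> pd.Series:
    """Assign up-regulated DEGs to clusters, resolving multi-cluster genes
    to the comparison with the highest ln fold change.

    ``deg_tables`` maps comparison name -> DE table; ``comparison_cluster``
    maps comparison name -> the cluster whose up-regulation it tests.
    A gene qualifies for a cluster when FDR <= 0.05, ln_fc > 0 and
    ``pct_in >= deg_pct``.
    """
    params = params or GRNParams()
    best: dict = {}
    for comp, tab in deg_tables.items():
        cluster = comparison_cluster[comp]
        up = tab[(tab["fdr"] <= 0.05) & (tab["ln_fc"] > 0)
                 & (tab["pct_in"] >= params.deg_pct)]
        for gene, lnfc in zip(up["gene"], up["ln_fc"]):
            if gene not in best or lnfc > best[gene][1]:
                best[gene] = (cluster, lnfc)
    return pd.Series({g: c for g, (c, _) in best.items()}, name="cluster",
                     dtype=object)


def cluster_subnetworks(net: GeneNetwork, deg_tables: dict,
                        comparison_cluster: dict, tf_genes: set,
                        params: GRNParams | None = None) -> GeneNetwork:
    """Cluster-specific subnetworks of a coexpression network.

    (1) candidate genes are up-regulated DEGs (FDR <= 0.05, expressed in at
    least ``deg_pct`` of cluster cells) from any supplied comparison;
    (2) multi-cluster DEGs go to the cluster of highest ln fold change;
    (3) panel TFs qualifying under the same rule are cluster TFs;
    (4) TFs with at least ``tf_neighbor_frac`` of their network neighbors in
    a cluster's DEG set are attached to that cluster;
    (5) connected components with fewer than ``min_component`` nodes are
    dropped.  Node attribute ``cluster`` is set on the returned subnetwork.
    """
    params = params or GRNParams()
    assignment = assign_degs_to_clusters(deg_tables, comparison_cluster,
                                         params)
    assignment = assignment[assignment.index.isin(net.nodes())]
    cluster_degs = {c: set(assignment.index[assignment == c])
                    for c in assignment.unique()}
    # rule (4): attach TFs by neighbor fraction (best cluster on ties)
    for node in net.nodes():
        if node in assignment.index or node not in tf_genes:
            continue
        nbrs = set(net.graph.neighbors(node))
        if not nbrs:
            continue
        fracs = {c: len(nbrs & degs) / len(nbrs)
                 for c, degs in cluster_degs.items()}
        if not fracs:
            continue
        best_c = max(sorted(fracs), key=lambda c: fracs[c])
        if fracs[best_c] >= params.tf_neighbor_frac:
            assignment.loc[node] = best_c
    keep = list(assignment.index)
    sub = net.subgraph(keep)
    for node, c in assignment.items():
        sub.graph.nodes[node]["cluster"] = c
    # rule (5)
    small = [n for comp in nx.connected_components(sub.graph)
             if len(comp) < params.min_component for n in comp]
    sub.graph.remove_nodes_from(small)
    return sub


def degree_distribution(net: GeneNetwork) -> tuple[pd.Series, pd.DataFrame]:
    """Exact per-node degrees plus a histogram with summary quantiles."""
    deg = net.degrees()
    if deg.empty:
        hist = pd.DataFrame(columns=["degree", "n_nodes"])
    else:
        counts = deg.value_counts().sort_index()
        hist = pd.DataFrame({"degree": counts.index, "n_nodes": counts.values})
        hist.attrs["quantiles"] = deg.quantile([0.25, 0.5, 0.75]).to_dict()
    return deg, hist


def recovered_true_edges(net: GeneNetwork, true_edges: pd.DataFrame) -> int:
    """Number of ground-truth TF->target pairs present (undirected) in a
    network — the recovery oracle used against simulations."""
    edge_set = net.edge_set()
    return sum(frozenset((tf, tg)) in edge_set
               for tf, tg in zip(true_edges["tf"], true_edges["target"]))
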