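"""Normalization, unsupervised clustering and rank-based differential
expression.

Expression values are log2(count / size_factor + 1) with the size factor
defaulting to the cell's library size over the median library size.
Clustering runs on the top principal components of the scaled log values,
either with Ward agglomeration (cluster number chosen by mean silhouette
unless fixed) or with Louvain communities on a kNN graph.  Differential
expression uses a two-sided Wilcoxon rank-sum test per gene (exact null for
small groups, tie-corrected normal approximation otherwise) with
Benjamini-Hochberg correction and a natural-log fold change of mean
normalized expression with a pseudocount of 1.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from ._stats import EXACT_MAX, bh_fdr, ranksum_test
from .types import (ClusterResult, ConfigurationError, CountMatrix, DataError,
                    DEParams)


def size_factors(counts: CountMatrix, method: str = "library") -> pd.Series:
    """Per-cell size factors.

    ``library``: library size over the median library size.  ``median-ratio``:
    DESeq-style median ratio to the geometric-mean reference gene profile
    (computed over genes expressed in every cell).
    """
    lib = counts.library_sizes().astype(float)
    if (lib == 0).any():
        raise DataError("cell(s) with zero library size")
    if method == "library":
        sf = lib / lib.median()
    elif method == "median-ratio":
        dense = counts.counts.toarray().astype(float)
        everywhere = (dense > 0).all(axis=1)
        if not everywhere.any():
            raise DataError("no gene expressed in every cell; "
                            "median-ratio size factors undefined")
        sub = dense[everywhere]
        ref = np.exp(np.log(sub).mean(axis=1))
        sf = pd.Series(np.median(sub / ref[:, None], axis=0),
                       index=counts.cells)
    else:
        raise ConfigurationError(f"unknown size-factor method {method!r}")
    return sf.rename("size_factor")


def normalize_log(counts: CountMatrix, size_factor_method: str = "library",
                  factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x cells."""
    sf = (factors.astype(float) if factors is not None
          else size_factors(counts, size_factor_method))
    dense = counts.counts.toarray().astype(float)
    return pd.DataFrame(np.log2(dense / sf.values[None, :] + 1.0),
                        index=counts.genes, columns=counts.cells)


def highly_variable_genes(norm: pd.DataFrame, n_top: int = 500) -> list:
    """Top genes by variance of log expression (ties by gene order)."""
    var = norm.values.var(axis=1)
    order = np.argsort(-var, kind="stable")[: min(n_top, norm.shape[0])]
    return [norm.index[i] for i in sorted(order)]


def _embed(norm: pd.DataFrame, n_pcs: int, seed: int,
           n_top_genes: int | None = 500) -> np.ndarray:
    if n_top_genes:
        norm = norm.loc[highly_variable_genes(norm, n_top_genes)]
    X = norm.values.T  # cells x genes
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_pcs = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    if n_pcs < 1:
        raise DataError("too few cells/genes for the embedding")
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)


def cluster_cells(norm: pd.DataFrame, method: str = "hierarchical_ward",
                  k: int | None = None, k_max: int = 8, n_pcs: int = 20,
                  n_neighbors: int = 15, resolution: float = 1.0,
                  n_top_genes: int | None = 500,
                  seed: int = 0) -> ClusterResult:
    """Cluster cells on the PCA embedding of scaled log expression.

    For ``hierarchical_ward`` the number of clusters is chosen by maximal
    mean silhouette over ``k in [2, k_max]`` unless ``k`` is fixed (ties
    toward smaller k); ``knn_graph_louvain`` uses Louvain communities on a
    shared-neighbor graph and ignores ``k``.
    """
    n_cells = norm.shape[1]
    if n_cells < 2:
        raise DataError("need at least two cells to cluster")
    if k is not None and k > n_cells:
        raise ConfigurationError(f"k={k} exceeds {n_cells} cells")
    if k == 1:
        labels = np.zeros(n_cells, dtype=int)
        return ClusterResult(pd.Series(labels, index=norm.columns,
                                       name="cluster"))
    emb = _embed(norm, n_pcs=n_pcs, seed=seed, n_top_genes=n_top_genes)
    if method == "hierarchical_ward":
        if k is not None:
            labels = AgglomerativeClustering(
                n_clusters=k, linkage="ward").fit_predict(emb)
        else:
            best_k, best_score = None, -np.inf
            for kk in range(2, min(k_max, n_cells - 1) + 1):
                lab = AgglomerativeClustering(
                    n_clusters=kk, linkage="ward").fit_predict(emb)
                score = silhouette_score(emb, lab)
                if score > best_score + 1e-12:  # ties toward smaller k
                    best_k, best_score = kk, score
            labels = AgglomerativeClustering(
                n_clusters=best_k, linkage="ward").fit_predict(emb)
    elif method == "knn_graph_louvain":
        nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n_cells))
        nn.fit(emb)
        _, idx = nn.kneighbors(emb)
        g = nx.Graph()
        g.add_nodes_from(range(n_cells))
        for i in range(n_cells):
            for j in idx[i, 1:]:
                g.add_edge(i, int(j))
        comms = nx.community.louvain_communities(
            g, resolution=resolution, seed=seed)
        labels = np.empty(n_cells, dtype=int)
        for c, members in enumerate(sorted(comms, key=lambda s: -len(s))):
            labels[list(members)] = c
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    # relabel clusters by order of first appearance for determinism
    remap, out = {}, np.empty(n_cells, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(lab, len(remap))
    return ClusterResult(pd.Series(out, index=norm.columns, name="cluster"))


def _ranksum_vectorized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected normal-approximation rank-sum p per row."""
    n1, n2 = a.shape[1], b.shape[1]
    both = np.hstack([a, b])
    ranks = scipy.stats.rankdata(both, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie correction per gene
    tie_term = np.zeros(both.shape[0])
    for i in range(both.shape[0]):
        _, cnt = np.unique(both[i], return_counts=True)
        tie_term[i] = (cnt ** 3 - cnt).sum()
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(w - mu) - 0.5) / np.sqrt(var)
    p = 2 * scipy.stats.norm.sf(z)
    p = np.where(var <= 0, 1.0, np.clip(p, 0.0, 1.0))
    return p


def differential_expression(norm: pd.DataFrame, labels: pd.Series,
                            contrast: tuple, params: DEParams | None = None
                            ) -> pd.DataFrame:
    """Rank-based DE between two cell groups.

    ``contrast`` is ``("one_vs_rest", cluster)`` or ``("pair", a, b)``.
    Returns one row per gene with ``ln_fc`` (natural-log fold change of mean
    normalized expression, pseudocount 1), two-sided rank-sum ``p``, BH
    ``fdr``, expressing-cell fractions and a ``significant`` flag at the
    thresholds in ``params``.
    """
    params = params or DEParams()
    labels = labels.reindex(norm.columns)
    if contrast[0] == "one_vs_rest":
        in_mask = (labels == contrast[1]).values
        out_mask = ~in_mask
    elif contrast[0] == "pair":
        in_mask = (labels == contrast[1]).values
        out_mask = (labels == contrast[2]).values
    else:
        raise ConfigurationError(f"unknown contrast {contrast[0]!r}")
    if in_mask.sum() == 0 or out_mask.sum() == 0:
        raise DataError("both contrast groups must be non-empty")
    a = norm.values[:, in_mask]
    b = norm.values[:, out_mask]
    # fold change on the de-logged normalized scale
    expr_a = np.expm1(a * np.log(2.0)).mean(axis=1)
    expr_b = np.expm1(b * np.log(2.0)).mean(axis=1)
    ln_fc = np.log(expr_a + 1.0) - np.log(expr_b + 1.0)
    pct_in = (a > 0).mean(axis=1)
    pct_out = (b > 0).mean(axis=1)
    if a.shape[1] <= EXACT_MAX and b.shape[1] <= EXACT_MAX:
        p = np.array([ranksum_test(a[i], b[i])[1]
                      for i in range(a.shape[0])])
    else:
        p = _ranksum_vectorized(a, b)
        flat = np.ptp(np.hstack([a, b]), axis=1) == 0
        p[flat] = 1.0
    fdr = bh_fdr(p)
    tab = pd.DataFrame({
        "gene": norm.index, "ln_fc": ln_fc, "p": p, "fdr": fdr,
        "pct_in": pct_in, "pct_out": pct_out})
    tab["significant"] = ((tab["fdr"] <= params.fdr_cut)
                          & (tab["ln_fc"].abs() >= params.lnfc_cut)
                          & (tab["pct_in"] >= params.min_pct))
    return tab.reset_index(drop=True)


def de_one_vs_rest(norm: pd.DataFrame, labels: pd.Series,
                   params: DEParams | None = None) -> dict[str, pd.DataFrame]:
    """One-vs-rest DE tables for every cluster, keyed ``"<c>_vs_rest"``."""
    tables = {}
    for c in sorted(pd.Series(labels).unique()):
        tables[f"{c}_vs_rest"] = differential_expression(
            norm, labels, ("one_vs_rest", c), params)
    return tables


def de_pairwise(norm: pd.DataFrame, labels: pd.Series,
                params: DEParams | None = None) -> dict[str, pd.DataFrame]:
    """Pairwise DE tables for every ordered cluster pair, keyed ``"<a>_vs_<b>"``."""
    tables = {}
    cl = sorted(pd.Series(labels).unique())
    for a in cl:
        for b in cl:
            if a != b:
                tables[f"{a}_vs_{b}"] = differential_expression(
                    norm, labels, ("pair", a, b), params)
    return tables
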