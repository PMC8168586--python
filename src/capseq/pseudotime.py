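"""Diffusion-map embedding and lineage/pseudotime ordering.

The diffusion map uses a Gaussian kernel with per-cell local bandwidths
(the distance to the ceil(n_neighbors/2)-th neighbor), density
normalization and row normalization to a Markov transition matrix; the
coordinates are the leading non-trivial eigenvectors scaled by their
eigenvalues, with the sign fixed so the largest-magnitude loading is
positive (a permutation-invariant convention).
Lineages are root-to-leaf paths of the minimum spanning tree over cluster
centroids in diffusion space; a cell's pseudotime on a lineage is the
normalized arc length of its orthogonal projection onto the piecewise
linear centroid path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.spatial

from .types import ConfigurationError, DataError


def diffusion_map(norm: pd.DataFrame, n_components: int = 3,
                  n_neighbors: int = 15, seed: int = 0) -> pd.DataFrame:
    """Diffusion-map coordinates of cells (rows of the result).

    ``norm`` is a genes x cells matrix of log-normalized expression.
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    X = norm.values.T  # cells x features
    n_cells = X.shape[0]
    if n_cells < n_components + 2:
        raise DataError("need at least n_components + 2 cells")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(X, metric="euclidean"))
    if np.all(d == 0):
        raise DataError("degenerate spectrum: all cells are identical")
    kth = int(np.ceil(n_neighbors / 2))
    kth = min(kth, n_cells - 1)
    sigma = np.sort(d, axis=1)[:, kth]
    sigma = np.maximum(sigma, 1e-12)
    K = np.exp(-(d ** 2) / (sigma[:, None] * sigma[None, :]))
    # density normalization removes sampling-density bias
    q = K.sum(axis=1)
    W = K / np.outer(q, q)
    deg = W.sum(axis=1)
    # symmetric conjugate of the Markov matrix for a stable eigenproblem
    S = W / np.sqrt(np.outer(deg, deg))
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(deg)[:, None]  # right eigenvectors of the Markov matrix
    coords = {}
    for k in range(1, n_components + 1):
        v = psi[:, k] * evals[k]
        # sign fixed so the largest-magnitude loading is positive; unlike a
        # first-nonzero rule this is invariant to permuting the cells
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[f"DC{k}"] = v
    return pd.DataFrame(coords, index=norm.columns)


@dataclass
class TrajectoryResult:
    """Lineage structure and pseudotime from a diffusion embedding."""

    coordinates: pd.DataFrame            # cells x DCs
    lineages: list                       # ordered cluster paths from root
    pseudotime: pd.DataFrame             # cells x lineages, NaN off-lineage
    weights: pd.DataFrame                # cells x lineages, rows sum to 1
    cell_pseudotime: pd.Series           # weighted mean over assigned lineages
    centroids: pd.DataFrame              # cluster centroids in diffusion space
    mst_edges: list


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> tuple[float, float]:
    """(distance, arc position in [0, |b-a|]) of p's projection onto [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t * float(np.linalg.norm(ab))


def fit_lineages(coordinates: pd.DataFrame, labels: pd.Series,
                 root_cluster) -> TrajectoryResult:
    """Order cells along MST lineages from a designated root cluster.

    Pseudotime on each lineage is arc length along the piecewise-linear
    centroid path, normalized to [0, 1]; cells attach to the tree edge whose
    segment they are nearest to and belong to every lineage through that
    edge (weights split equally).
    """
    labels = labels.reindex(coordinates.index)
    clusters = sorted(labels.unique().tolist())
    if root_cluster not in clusters:
        raise ConfigurationError(f"root cluster {root_cluster!r} not in labels")
    cent = coordinates.groupby(labels).mean()
    X = coordinates.values
    if len(clusters) == 1:
        dc1 = coordinates.iloc[:, 0].values.astype(float)
        rng = dc1.max() - dc1.min()
        pt = (dc1 - dc1.min()) / rng if rng > 0 else np.zeros_like(dc1)
        # orient so the root centroid sits at pseudotime 0 (trivially true)
        ptf = pd.DataFrame({0: pt}, index=coordinates.index)
        w = pd.DataFrame({0: np.ones(len(dc1))}, index=coordinates.index)
        return TrajectoryResult(coordinates, [[root_cluster]], ptf, w,
                                ptf[0].rename("pseudotime"), cent, [])
    # MST over centroids (Euclidean, complete graph)
    g = nx.Graph()
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            g.add_edge(a, b, weight=float(np.linalg.norm(
                cent.loc[a].values - cent.loc[b].values)))
    mst = nx.minimum_spanning_tree(g)
    leaves = [c for c in clusters
              if c != root_cluster and mst.degree(c) == 1]
    if not leaves:  # root is the only leaf: single path back
        leaves = [c for c in clusters if c != root_cluster]
    lineages = [nx.shortest_path(mst, root_cluster, leaf) for leaf in leaves]
    lineages.sort(key=lambda p: tuple(map(str, p)))

    # attach each cell to its nearest tree-edge segment
    tree_edges = sorted(mst.edges, key=lambda e: tuple(map(str, e)))
    seg_pts = {tuple(e): (cent.loc[e[0]].values, cent.loc[e[1]].values)
               for e in tree_edges}
    nearest_edge = []
    for i in range(X.shape[0]):
        best, best_d = None, np.inf
        for e in tree_edges:
            a, b = seg_pts[tuple(e)]
            dist, _ = _project_to_segment(X[i], a, b)
            if dist < best_d - 1e-15:
                best, best_d = e, dist
        nearest_edge.append(tuple(best))

    # arc-length pseudotime per lineage
    pt = pd.DataFrame(np.nan, index=coordinates.index,
                      columns=range(len(lineages)))
    wt = pd.DataFrame(0.0, index=coordinates.index,
                      columns=range(len(lineages)))
    lineage_edges = []
    for li, path in enumerate(lineages):
        edges = [frozenset((path[j], path[j + 1]))
                 for j in range(len(path) - 1)]
        lineage_edges.append(edges)
        pts = [cent.loc[c].values for c in path]
        seg_len = [float(np.linalg.norm(pts[j + 1] - pts[j]))
                   for j in range(len(pts) - 1)]
        total = sum(seg_len)
        offsets = np.concatenate([[0.0], np.cumsum(seg_len)])
        for i, cell in enumerate(coordinates.index):
            if frozenset(nearest_edge[i]) not in edges:
                continue
            # project onto the whole path, take the nearest segment's arc
            best_arc, best_d = None, np.inf
            for j in range(len(pts) - 1):
                dist, arc = _project_to_segment(X[i], pts[j], pts[j + 1])
                if dist < best_d - 1e-15:
                    best_d, best_arc = dist, offsets[j] + arc
            pt.loc[cell, li] = best_arc / total if total > 0 else 0.0
    for i, cell in enumerate(coordinates.index):
        member = [li for li in range(len(lineages))
                  if frozenset(nearest_edge[i]) in lineage_edges[li]]
        for li in member:
            wt.loc[cell, li] = 1.0 / len(member)
    agg = (pt.fillna(0.0) * wt).sum(axis=1) / wt.sum(axis=1)
    return TrajectoryResult(coordinates, lineages, pt, wt,
                            agg.rename("pseudotime"), cent, tree_edges)


def expression_along_pseudotime(norm: pd.DataFrame, pseudotime: pd.Series,
                                genes: list, window: int = 20
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rolling-mean expression profiles over pseudotime-ordered cells.

    Returns ``(smoothed, centered)``: genes x ordered-cells tables of
    rolling-mean log2 values and the same after per-gene mean centering
    (the heatmap export convention).  ``window=1`` reproduces the raw
    ordered values.
    """
    missing = [g for g in genes if g not in norm.index]
    if missing:
        raise DataError(f"genes not present: {missing[:5]}")
    pt = pseudotime.reindex(norm.columns).dropna()
    if window > len(pt):
        raise ConfigurationError("window larger than the number of cells")
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    order = pt.sort_values(kind="stable").index
    values = norm.loc[genes, order]
    smoothed = values.T.rolling(window, min_periods=1, center=True).mean().T
    centered = smoothed.sub(smoothed.mean(axis=1), axis=0)
    return smoothed, centered
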