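"""Shared domain types for the capture-enrichment analysis pipeline.

The universal unit of exchange between stages is :class:`CountMatrix`, a
sparse genes x cells matrix with ordered identifiers and per-cell/per-gene
annotation tables.  :class:`CapturePanel` describes the targeted gene set
(e.g. a transcription-factor panel) together with the spike-in controls,
only a subset of which is covered by capture probes.  :class:`GeneNetwork`
wraps an undirected ``networkx`` graph with signed correlation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed external file (bad header, dimensions, negative entries...)."""


class AlignmentError(ValueError):
    """Paired inputs do not share the required gene/cell universe or order."""


class ConfigurationError(ValueError):
    """Invalid parameter or configuration value."""


class DataError(ValueError):
    """Data-dependent failure (empty result, zero library, degenerate input)."""


class CountMatrix:
    """Sparse genes x cells expression matrix with ordered annotations.

    Parameters
    ----------
    genes, cells
        Ordered, unique identifiers for rows and columns.
    counts
        Non-negative matrix (dense or sparse), shape ``(len(genes), len(cells))``.
        Raw counts are integers; derived matrices (e.g. library-rescaled
        imputed values) may be fractional.
    cell_meta, gene_meta
        Optional per-cell / per-gene annotation tables indexed like
        ``cells`` / ``genes``.  A ``library_size`` column is (re)computed on
        construction so it always equals the column sums.
    """

    def __init__(self, genes, cells, counts, cell_meta=None, gene_meta=None,
                 validate=True):
        self.genes = [str(g) for g in genes]
        self.cells = [str(c) for c in cells]
        self.counts = sp.csr_matrix(counts)
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=pd.Index(self.cells, name="cell"))
        else:
            cell_meta = pd.DataFrame(cell_meta).copy()
            cell_meta.index = pd.Index(self.cells, name="cell")
        if gene_meta is None:
            gene_meta = pd.DataFrame(index=pd.Index(self.genes, name="gene"))
        else:
            gene_meta = pd.DataFrame(gene_meta).copy()
            gene_meta.index = pd.Index(self.genes, name="gene")
        self.cell_meta = cell_meta
        self.gene_meta = gene_meta
        self.cell_meta["library_size"] = np.asarray(
            self.counts.sum(axis=0)).ravel()
        if validate:
            self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell identifiers")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count entries")

    # -- basic accessors ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def library_sizes(self) -> pd.Series:
        """Per-cell library size = column sum of counts."""
        return pd.Series(np.asarray(self.counts.sum(axis=0)).ravel(),
                         index=self.cells, name="library_size")

    def detected_genes_per_cell(self, genes: Sequence[str] | None = None
                                ) -> pd.Series:
        """Number of genes with count > 0 per cell, optionally restricted."""
        m = self.counts if genes is None else self._rows(genes)
        return pd.Series(np.asarray((m > 0).sum(axis=0)).ravel(),
                         index=self.cells, name="n_detected")

    def _rows(self, genes: Sequence[str]) -> sp.csr_matrix:
        idx = self.gene_index()
        rows = [idx[g] for g in genes if g in idx]
        return self.counts[rows, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.genes,
                            columns=self.cells)

    # -- subsetting (order-stable) --------------------------------------
    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        keep = set(map(str, cells))
        pos = [i for i, c in enumerate(self.cells) if c in keep]
        return CountMatrix(
            self.genes, [self.cells[i] for i in pos], self.counts[:, pos],
            cell_meta=self.cell_meta.iloc[pos].drop(
                columns="library_size", errors="ignore"),
            gene_meta=self.gene_meta)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        keep = set(map(str, genes))
        pos = [i for i, g in enumerate(self.genes) if g in keep]
        return CountMatrix(
            [self.genes[i] for i in pos], self.cells, self.counts[pos, :],
            cell_meta=self.cell_meta.drop(columns="library_size",
                                          errors="ignore"),
            gene_meta=self.gene_meta.iloc[pos])

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.genes, self.cells, self.counts.copy(),
                           cell_meta=self.cell_meta.drop(
                               columns="library_size", errors="ignore"),
                           gene_meta=self.gene_meta, validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CountMatrix({self.n_genes} genes x {self.n_cells} cells, "
                f"{self.counts.nnz} non-zero)")


@dataclass
class CapturePanel:
    """Targeted gene identifiers plus spike-in controls.

    ``spike_on_panel`` is the subset of spike-ins covered by capture probes
    (56 of the 92 ERCC species in the transcription-factor design).
    """

    target_genes: set
    spike_ids: set = field(default_factory=set)
    spike_on_panel: set = field(default_factory=set)

    def __post_init__(self):
        self.target_genes = set(map(str, self.target_genes))
        self.spike_ids = set(map(str, self.spike_ids))
        self.spike_on_panel = set(map(str, self.spike_on_panel))
        if not self.target_genes:
            raise ConfigurationError("capture panel has no target genes")
        if not self.spike_on_panel <= self.spike_ids:
            raise ConfigurationError("spike_on_panel must be a subset of spike_ids")
        if self.target_genes & self.spike_ids:
            raise ConfigurationError("target genes and spike-ins must be disjoint")


@dataclass
class QCThresholds:
    """Cell and gene quality-control thresholds.

    Defaults follow the filters used on real Smart-seq2 libraries: cells must
    express at least 2000 genes, have at least 0.5 million read pairs, their
    200 most expressed genes must not exceed 50% of all counts, and spike-ins
    must not exceed 14% of all counts; genes are retained when their mean
    count over cells exceeds 1.
    """

    min_genes_per_cell: int = 2000
    min_library_size: float = 500_000
    max_top200_fraction: float = 0.50
    max_spike_fraction: float = 0.14
    min_gene_mean_count: float = 1.0

    def __post_init__(self):
        for name in ("max_top200_fraction", "max_spike_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.min_genes_per_cell <= 0 or self.min_library_size <= 0:
            raise ConfigurationError("count thresholds must be positive")


@dataclass
class DEParams:
    """Differential-expression significance thresholds.

    ``lnfc_cut`` is a natural-log fold-change cutoff; ``min_pct`` is the
    fraction of in-group cells required to express a gene (0.5 when selecting
    genes for cluster subnetworks, 0 for general DE).
    """

    fdr_cut: float = 0.05
    lnfc_cut: float = 0.5
    min_pct: float = 0.0

    def __post_init__(self):
        if not 0 <= self.fdr_cut <= 1 or not 0 <= self.min_pct <= 1:
            raise ConfigurationError("fdr_cut and min_pct must lie in [0, 1]")
        if self.lnfc_cut < 0:
            raise ConfigurationError("lnfc_cut must be non-negative")


@dataclass
class GRNParams:
    """Coexpression-network thresholds (|r| cutoff, BH alpha, subnetwork rules)."""

    corr_threshold: float = 0.8
    sig_alpha: float = 0.05
    min_component: int = 3
    deg_pct: float = 0.5
    tf_neighbor_frac: float = 0.2

    def __post_init__(self):
        if not 0 <= self.corr_threshold <= 1:
            raise ConfigurationError("corr_threshold must lie in [0, 1]")
        if not 0 <= self.sig_alpha <= 1:
            raise ConfigurationError("sig_alpha must lie in [0, 1]")
        if self.min_component < 1:
            raise ConfigurationError("min_component must be >= 1")
        if not 0 <= self.deg_pct <= 1 or not 0 <= self.tf_neighbor_frac <= 1:
            raise ConfigurationError("fractions must lie in [0, 1]")


class GeneNetwork:
    """Undirected coexpression network with signed edge weights.

    Nodes carry ``is_tf`` flags and an optional ``cluster`` assignment;
    self-loops are rejected and edge weights are the signed correlation that
    created the edge.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], nodes: Iterable[str] = (),
                   tf_genes: Iterable[str] = ()) -> "GeneNetwork":
        net = cls()
        tf = set(tf_genes)
        for n in nodes:
            net.add_node(n, is_tf=n in tf)
        for e in edges:
            a, b = e[0], e[1]
            w = e[2] if len(e) > 2 else 1.0
            net.add_edge(a, b, w)
            for n in (a, b):
                net.graph.nodes[n].setdefault("is_tf", n in tf)
        return net

    def add_node(self, name: str, is_tf: bool = False, cluster=None) -> None:
        self.graph.add_node(str(name), is_tf=bool(is_tf), cluster=cluster)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        a, b = str(a), str(b)
        if a == b:
            raise FormatError(f"self-loop on node {a!r}")
        self.graph.add_edge(a, b, weight=float(weight))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degrees(self) -> pd.Series:
        d = dict(self.graph.degree())
        return pd.Series(d, dtype=int, name="degree")

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(str(a), str(b))

    def subgraph(self, nodes: Iterable[str]) -> "GeneNetwork":
        return GeneNetwork(self.graph.subgraph(list(nodes)).copy())

    def node_table(self) -> pd.DataFrame:
        deg = dict(self.graph.degree())
        rows = [{"gene": n, "degree": deg[n],
                 "is_tf": bool(self.graph.nodes[n].get("is_tf", False)),
                 "cluster": self.graph.nodes[n].get("cluster")}
                for n in self.graph.nodes]
        return pd.DataFrame(rows, columns=["gene", "degree", "is_tf", "cluster"])

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class ClusterResult:
    """Per-cell cluster labels plus per-comparison DEG tables.

    ``deg_tables`` maps a comparison name (e.g. ``"1_vs_rest"``,
    ``"1_vs_2"``) to a table with columns
    ``gene, ln_fc, p, fdr, pct_in, pct_out, significant``.
    """

    labels: pd.Series
    deg_tables: dict = field(default_factory=dict)

    def clusters(self) -> list:
        return sorted(self.labels.unique().tolist())


def align_check(a: CountMatrix, b: CountMatrix, genes: bool = True,
                cells: bool = True) -> None:
    """Raise :class:`AlignmentError` unless the two matrices share the
    required (ordered) gene/cell universe."""
    if cells and a.cells != b.cells:
        raise AlignmentError("cell sets/order differ between matrices")
    if genes and a.genes != b.genes:
        raise AlignmentError("gene sets/order differ between matrices")
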