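"""Readers and writers for the pipeline's external formats.

Count matrices are exchanged either as Matrix Market triplet files with
companion gene/cell TSVs (``<stem>.mtx`` + ``<stem>.genes.tsv`` +
``<stem>.cells.tsv``, genes as rows, 1-based coordinates, 10x-style) or as a
dense genes x cells TSV with a header row of cell identifiers.  Gene sets
use GMT; networks use an edge-list TSV (``gene_a   gene_b   weight``) or
GraphML.  Gene identifiers are opaque strings.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CapturePanel, CountMatrix, FormatError, GeneNetwork


def _companions(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.tsv"), stem.with_suffix(".cells.tsv")


def _validate_triplet_lines(path: Path) -> None:
    """Scan a Matrix Market triplet file so format errors name the line."""
    with open(path) as fh:
        lines = fh.readlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines)
            if not ln.startswith("%") and ln.strip()]
    if not body:
        raise FormatError(f"{path}: empty Matrix Market file")
    (hdr_no, hdr), entries = body[0], body[1:]
    parts = hdr.split()
    if len(parts) != 3:
        raise FormatError(f"{path}:{hdr_no}: malformed size header {hdr!r}")
    try:
        n_rows, n_cols, _ = (int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"{path}:{hdr_no}: malformed size header {hdr!r}") from exc
    for no, ln in entries:
        p = ln.split()
        if len(p) != 3:
            raise FormatError(f"{path}:{no}: expected 'row col value', got {ln!r}")
        try:
            r, c, v = int(p[0]), int(p[1]), float(p[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{no}: non-numeric entry {ln!r}") from exc
        if not (1 <= r <= n_rows and 1 <= c <= n_cols):
            raise FormatError(f"{path}:{no}: coordinate ({r}, {c}) outside "
                              f"{n_rows} x {n_cols}")
        if v < 0:
            raise FormatError(f"{path}:{no}: negative entry {v}")


def read_counts(path, fmt: str = "auto") -> CountMatrix:
    """Read a count matrix from ``mtx_triplet`` or ``dense_tsv`` format.

    ``fmt="auto"`` dispatches on the file suffix (``.mtx`` vs anything else).
    Round-trips bit-exactly with :func:`write_counts`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mtx_triplet" if path.suffix == ".mtx" else "dense_tsv"
    if fmt == "mtx_triplet":
        genes_path, cells_path = _companions(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"missing companion annotation file {p}")
        _validate_triplet_lines(path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        genes_df = pd.read_csv(genes_path, sep="\t", index_col=0)
        cells_df = pd.read_csv(cells_path, sep="\t", index_col=0)
        genes = genes_df.index.astype(str).tolist()
        cells = cells_df.index.astype(str).tolist()
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{path}: matrix is {mat.shape[0]} x {mat.shape[1]} but "
                f"annotations give {len(genes)} genes x {len(cells)} cells")
        return CountMatrix(genes, cells, sp.csr_matrix(mat),
                           cell_meta=cells_df, gene_meta=genes_df)
    if fmt == "dense_tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if (df.values < 0).any():
            bad = df.index[(df.values < 0).any(axis=1)][0]
            raise FormatError(f"{path}: negative entry in row {bad!r}")
        return CountMatrix(df.index.astype(str), df.columns.astype(str),
                           df.values)
    raise FormatError(f"unknown count-matrix format {fmt!r}")


def write_counts(cm: CountMatrix, path, fmt: str = "auto") -> Path:
    """Write a count matrix; see :func:`read_counts` for the dialects."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "auto":
        fmt = "mtx_triplet" if path.suffix == ".mtx" else "dense_tsv"
    if fmt == "mtx_triplet":
        coo = sp.coo_matrix(cm.counts)
        integral = coo.nnz == 0 or np.allclose(coo.data, np.round(coo.data))
        scipy.io.mmwrite(path, coo, field="integer" if integral else "real")
        genes_path, cells_path = _companions(path)
        cm.gene_meta.to_csv(genes_path, sep="\t")
        cm.cell_meta.to_csv(cells_path, sep="\t")
    elif fmt == "dense_tsv":
        cm.to_frame().to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown count-matrix format {fmt!r}")
    return path


def read_gene_sets(path) -> dict[str, set]:
    """Read named gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{no}: GMT line needs name, description and at "
                    f"least one member ({len(fields)} fields)")
            name, members = fields[0], {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}:{no}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
    return path


NETWORK_COLUMNS = ["gene_a", "gene_b", "weight"]


def write_network(net: GeneNetwork, path, fmt: str = "edge_tsv") -> Path:
    """Write a network as an edge-list TSV or GraphML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "edge_tsv":
        rows = [(a, b, net.graph.edges[a, b].get("weight", 1.0))
                for a, b in net.graph.edges]
        pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(
            path, sep="\t", index=False)
    elif fmt == "graphml":
        g = net.graph.copy()
        for n, data in g.nodes(data=True):  # GraphML cannot encode None
            for k in [k for k, v in data.items() if v is None]:
                del data[k]
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {fmt!r}")
    return path


def read_network(path, fmt: str = "edge_tsv") -> GeneNetwork:
    path = Path(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        net = GeneNetwork()
        for a, b, w in df.itertuples(index=False):
            net.add_edge(str(a), str(b), float(w))
        return net
    if fmt == "graphml":
        return GeneNetwork(nx.read_graphml(path))
    raise FormatError(f"unknown network format {fmt!r}")


def read_panel(path) -> CapturePanel:
    """Read a capture panel from a TSV with columns ``gene`` and optional
    ``role`` (``target`` | ``spike`` | ``spike_on_panel``)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing 'gene' column")
    role = df["role"] if "role" in df.columns else pd.Series(
        "target", index=df.index)
    targets = set(df.loc[role == "target", "gene"].astype(str))
    on_panel = set(df.loc[role == "spike_on_panel", "gene"].astype(str))
    spikes = set(df.loc[role.str.startswith("spike"), "gene"].astype(str))
    return CapturePanel(targets, spikes, on_panel)


def write_panel(panel: CapturePanel, path) -> Path:
    rows = [(g, "target") for g in sorted(panel.target_genes)]
    rows += [(s, "spike_on_panel" if s in panel.spike_on_panel else "spike")
             for s in sorted(panel.spike_ids)]
    pd.DataFrame(rows, columns=["gene", "role"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_tf_targets(path) -> pd.DataFrame:
    """Read a TF->target table (TSV with columns ``tf, target`` and one of
    ``weight`` or ``p``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target"} <= set(df.columns):
        raise FormatError(f"{path}: needs 'tf' and 'target' columns")
    if not ({"weight", "p"} & set(df.columns)):
        raise FormatError(f"{path}: needs a 'weight' or 'p' column")
    return df
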