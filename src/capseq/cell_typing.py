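"""Marker derivation from reference profiles and hypergeometric cell typing.

Reference profiles are consumed as a mean-expression-per-type table
(genes x types).  A gene becomes a candidate marker for the type in which
it is most expressed, is removed when another type expresses it at more
than ``1/fold_cutoff`` of the own-type level (the "highly expressed in
other cell types" rule with a twofold cutoff by default), and marker sets
are kept pairwise disjoint.  Cluster DEG sets are then scored against the
marker sets with an upper-tail hypergeometric test and BH correction over
all (cluster, type) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_fdr, hypergeom_upper
from .types import DataError


@dataclass
class MarkerTable:
    """Pairwise-disjoint marker gene sets per cell type."""

    markers: dict  # type -> set of genes
    provenance: dict = field(default_factory=dict)  # gene -> source id

    def __post_init__(self):
        seen: set = set()
        for t, genes in self.markers.items():
            overlap = seen & set(genes)
            if overlap:
                raise DataError(
                    f"marker sets are not disjoint (e.g. {sorted(overlap)[:3]})")
            seen |= set(genes)

    def all_markers(self) -> set:
        out: set = set()
        for genes in self.markers.values():
            out |= set(genes)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, g, self.provenance.get(g, ""))
                for t, genes in self.markers.items() for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["type", "gene", "source"])


def derive_markers(profiles: pd.DataFrame, fold_cutoff: float = 2.0,
                   candidate_sets: dict | None = None,
                   source: str = "reference") -> MarkerTable:
    """Derive unique marker sets from a genes x types mean-expression table.

    Parameters
    ----------
    profiles
        Mean expression per type; needs at least two type columns.
    fold_cutoff
        A candidate for its best type is dropped when the maximal expression
        in any other type exceeds own-type expression / ``fold_cutoff``.
    candidate_sets
        Optional type -> gene-set mapping (e.g. significance-filtered DE
        results from replicate-level references); when given, a gene is only
        considered for types whose candidate set contains it.
    """
    if profiles.shape[1] < 2:
        raise DataError("need at least two cell types in the reference")
    markers: dict = {t: set() for t in profiles.columns}
    vals = profiles.values.astype(float)
    types = list(profiles.columns)
    for gi, gene in enumerate(profiles.index):
        row = vals[gi]
        order = np.argsort(-row, kind="stable")
        best = order[0]
        if row[best] <= 0:
            continue
        if candidate_sets is not None and gene not in candidate_sets.get(
                types[best], set()):
            continue
        others = np.delete(row, best)
        if others.size and others.max() > row[best] / fold_cutoff:
            continue  # highly expressed elsewhere
        # a tie for the top type means the gene is not unique to one type
        if others.size and np.isclose(others.max(), row[best]):
            continue
        markers[types[best]].add(gene)
    provenance = {g: source for s in markers.values() for g in s}
    return MarkerTable(markers, provenance)


def score_cluster_types(cluster_degs: dict, markers: MarkerTable,
                        universe: set) -> pd.DataFrame:
    """Hypergeometric overlap test of cluster DEG sets against marker sets.

    For each (cluster, type): ``p = P(X >= k)`` with ``N = |universe|``,
    ``K = |markers of type ∩ universe|``, ``n = |cluster DEGs ∩ universe|``
    and ``k`` the overlap; BH correction runs over all pairs.  DEGs and
    markers outside the universe are intersected away and the intersected
    sizes are what the table reports.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty gene universe")
    rows = []
    for cluster, degs in cluster_degs.items():
        degs_u = set(degs) & universe
        for ctype, mset in markers.markers.items():
            mset_u = set(mset) & universe
            k = len(degs_u & mset_u)
            p = hypergeom_upper(k, len(universe), len(mset_u), len(degs_u))
            rows.append((cluster, ctype, k, len(degs_u), len(mset_u), p))
    tab = pd.DataFrame(rows, columns=["cluster", "type", "overlap",
                                      "n_degs", "n_markers", "p"])
    tab["fdr"] = bh_fdr(tab["p"].values) if len(tab) else []
    return tab
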