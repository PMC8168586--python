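"""Network enrichment analysis and gene-set statistics.

NEA tests the connectivity of a gene set to the rest of a network: the
observed statistic is the number of edges with at least one endpoint in the
set, and the null is generated by degree-preserving edge randomization.
The randomizer repeatedly picks two edges uniformly at random and rewires
them (rejecting self-loops and duplicate edges), a symmetric Markov chain
whose stationary distribution is uniform over simple graphs with the given
degree sequence.  The module also provides Fisher 2x2 target enrichment,
hypergeometric TF-PPI term enrichment with BH correction, the exact paired
Wilcoxon signed-rank comparison, and the TF->target evidence filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._stats import bh_fdr, hypergeom_upper, signed_rank_test
from .types import DataError, FormatError, GeneNetwork


@dataclass
class EnrichmentResult:
    """Permutation-test outcome for a gene set's network connectivity."""

    observed: float
    null_mean: float
    null_sd: float
    z: float | None  # None when the null is degenerate (sd = 0)
    p: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        assert 0 < self.p <= 1


def incident_edge_count(net: GeneNetwork, gene_set: set) -> int:
    """Edges with at least one endpoint in the gene set."""
    gs = set(gene_set)
    return sum(1 for a, b in net.graph.edges if a in gs or b in gs)


def degree_preserving_permutation(edges: list, rng: np.random.Generator,
                                  n_attempts: int | None = None
                                  ) -> list:
    """Uniform degree-preserving randomization by double edge swaps.

    ``edges`` is a list of 2-tuples; a copy rewired in place is returned.
    Each attempt draws two distinct edges and one of the two rewirings at
    random and rejects moves creating self-loops or duplicate edges, so the
    chain is symmetric with a uniform stationary distribution over simple
    graphs with the same degree sequence.
    """
    edges = [tuple(e) for e in edges]
    m = len(edges)
    if m < 2:
        return edges
    present = {frozenset(e) for e in edges}
    attempts = n_attempts if n_attempts is not None else 10 * m
    # pre-drawn randomness: edge pairs and rewiring orientation
    ii = rng.integers(0, m, size=attempts)
    jj = rng.integers(0, m - 1, size=attempts)
    jj = np.where(jj >= ii, jj + 1, jj)  # uniform pair without replacement
    flips = rng.random(attempts) < 0.5
    for t in range(attempts):
        i, j = int(ii[t]), int(jj[t])
        u, v = edges[i]
        x, y = edges[j]
        if flips[t]:
            new1, new2 = (u, x), (v, y)
        else:
            new1, new2 = (u, y), (v, x)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        f1, f2 = frozenset(new1), frozenset(new2)
        if f1 == f2 or f1 in present or f2 in present:
            continue
        present.discard(frozenset(edges[i]))
        present.discard(frozenset(edges[j]))
        present.add(f1)
        present.add(f2)
        edges[i], edges[j] = new1, new2
    return edges


def nea(net: GeneNetwork, gene_set: set, n_perm: int = 1000, seed: int = 0,
        swaps_per_edge: int = 10) -> EnrichmentResult:
    """Network enrichment analysis of a gene set's connectivity.

    Empirical p uses the add-one rule, ``(1 + #{null >= obs}) / (1 + n_perm)``;
    z is reported against the permutation null and flagged ``None`` when the
    null is degenerate.  Deterministic under ``seed``.
    """
    gs = set(gene_set) & set(net.nodes())
    if not gs:
        raise DataError("gene set does not intersect the network nodes")
    if n_perm < 1:
        raise DataError("need at least one permutation")
    rng = np.random.default_rng(seed)
    edges = list(net.graph.edges)
    observed = incident_edge_count(net, gs)
    attempts = swaps_per_edge * len(edges)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = degree_preserving_permutation(edges, rng, attempts)
        null[k] = sum(1 for a, b in perm if a in gs or b in gs)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_perm)
    return EnrichmentResult(observed=float(observed), null_mean=null_mean,
                            null_sd=null_sd, z=z, p=p,
                            n_permutations=n_perm, seed=seed)


def fisher_target_enrichment(nodes: set, targets: set, universe: set,
                             other_nodes: set | None = None
                             ) -> tuple[float, float, pd.DataFrame]:
    """Fisher's exact test of target-gene enrichment.

    With ``other_nodes=None`` the 2x2 table crosses network membership
    (within the universe) against target status; otherwise it compares the
    target fractions of two node sets directly.  Returns
    ``(odds_ratio, two_sided_p, table)``; a zero margin gives p = 1 and a
    NaN odds ratio.
    """
    universe = set(universe)
    nodes = set(nodes) & universe
    targets = set(targets) & universe
    if other_nodes is None:
        a = len(nodes & targets)
        b = len(nodes - targets)
        c = len(targets - nodes)
        d = len(universe - nodes - targets)
    else:
        other = set(other_nodes) & universe
        a = len(nodes & targets)
        b = len(nodes - targets)
        c = len(other & targets)
        d = len(other - targets)
    table = pd.DataFrame([[a, b], [c, d]],
                         index=["in", "out"], columns=["target", "non_target"])
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0, table
    odds, p = scipy.stats.fisher_exact([[a, b], [c, d]],
                                       alternative="two-sided")
    return float(odds), float(p), table


def tfppi_enrichment(subnet_genes: dict, gene_sets: dict, universe: set
                     ) -> pd.DataFrame:
    """Hypergeometric enrichment of cluster subnetworks in TF-PPI terms.

    ``subnet_genes`` maps cluster -> gene set; ``gene_sets`` is a GMT-style
    term -> members mapping.  Terms with no member in the universe are
    skipped and recorded in ``table.attrs["skipped_terms"]``; BH runs within
    each cluster.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty gene universe")
    rows, skipped = [], []
    for cluster, genes in subnet_genes.items():
        genes_u = set(genes) & universe
        for term, members in gene_sets.items():
            members_u = set(members) & universe
            if not members_u:
                skipped.append(term)
                continue
            overlap = genes_u & members_u
            p = hypergeom_upper(len(overlap), len(universe), len(members_u),
                                len(genes_u))
            rows.append((cluster, term, len(overlap), len(members_u),
                         len(genes_u), p, ";".join(sorted(overlap))))
    tab = pd.DataFrame(rows, columns=["cluster", "term", "overlap",
                                      "term_size", "subnet_size", "p",
                                      "overlap_genes"])
    if len(tab):
        tab["fdr"] = np.concatenate([
            bh_fdr(sub["p"].values)
            for _, sub in tab.groupby("cluster", sort=False)])
    else:
        tab["fdr"] = []
    tab.attrs["skipped_terms"] = sorted(set(skipped))
    return tab


def paired_term_comparison(pre_counts, post_counts) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired per-term gene
    counts (pre vs post).  Returns ``(W_plus, p)``; all-zero differences
    give p = 1."""
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.shape != post.shape:
        raise DataError("paired vectors must have the same length/order")
    return signed_rank_test(post - pre)


def filter_tf_targets(weight_table: pd.DataFrame | None = None,
                      p_table: pd.DataFrame | None = None,
                      min_weight: float = 0.1,
                      max_p: float = 1e-7) -> set:
    """Union of evidence-filtered TF->target links.

    Weight-based links are kept when ``weight >= min_weight`` (inclusive);
    p-value-based links when ``p < max_p`` (strict).  Duplicates collapse.
    """
    links: set = set()
    if weight_table is not None:
        for col in ("tf", "target", "weight"):
            if col not in weight_table.columns:
                raise FormatError(f"weight table missing column {col!r}")
        kept = weight_table[weight_table["weight"] >= min_weight]
        links |= {(str(t), str(g)) for t, g in zip(kept["tf"], kept["target"])}
    if p_table is not None:
        for col in ("tf", "target", "p"):
            if col not in p_table.columns:
                raise FormatError(f"p table missing column {col!r}")
        kept = p_table[p_table["p"] < max_p]
        links |= {(str(t), str(g)) for t, g in zip(kept["tf"], kept["target"])}
    return links
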