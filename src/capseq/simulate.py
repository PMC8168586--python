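"""Paired pre-/post-capture count simulator with known ground truth.

The generator emulates the statistical structure of a targeted-capture
experiment on single-cell libraries:

* cluster-structured negative-binomial counts with extra zero-inflation
  (dropout) that is worse for lowly expressed genes — the regime in which
  transcription factors live;
* a branching latent trajectory: each cluster carries a gene "program"
  (a few panel TF hubs plus downstream targets) whose effect ramps
  log-linearly along the cell's position on its branch, the root cluster's
  program decaying and leaf programs rising;
* ERCC-like spike-ins with constant expected expression in every cell, only
  a subset of which is covered by capture probes (56 of 92 by default);
* a capture operation that multiplies the sampling probability of on-panel
  genes (and on-panel spikes) by an enrichment factor ``E`` and resamples
  the cell's library to a ``post_depth_ratio``-fold larger depth.

Dropout is modelled as a per-(gene, cell) Bernoulli mask on the cell's
library composition that is *shared* between the pre- and post-capture
draws: capture rescues sampling zeros (transcripts present in the library
but unsequenced pre-capture) but cannot recover transcripts the library
never contained.  With ``E = 1`` and ``post_depth_ratio = 1`` the pre and
post matrices are therefore exchangeable draws from the same composition.

All expectations used by the closed-form helpers
(:func:`expected_on_target_fraction`,
:func:`expected_genewise_log2_enrichment`) follow directly from the
multinomial construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import CapturePanel, ConfigurationError, CountMatrix, GeneNetwork


@dataclass
class SimulationConfig:
    """Study conditions for the paired pre/post-capture generator.

    Defaults are sized for desk-scale experiments: 300 cells, 2000
    endogenous genes of which a 150-gene panel of lowly expressed TFs, three
    clusters on a root + two-leaf branching topology, a 4x program effect,
    100x on-target enrichment and 4x deeper post-capture libraries (the
    post/pre depth ratio observed for real captured libraries).
    """

    n_cells: int = 300
    n_genes: int = 2000
    n_panel: int = 150
    n_clusters: int = 3
    branch_topology: dict | None = None  # cluster -> parent (root maps to None)
    base_mean: float = 2.0
    dispersion: float = 3.0  # NB size parameter; var = mu + mu^2/size
    program_fc: float = 4.0
    enrichment_factor: float = 100.0
    post_depth_ratio: float = 4.0
    n_spikes: int = 92
    n_spikes_on_panel: int = 56
    dropout_logit_slope: float = 4.0
    dropout_logit_intercept: float = -2.5
    seed: int = 0
    # gene-level heterogeneity and program sizing
    gene_mean_sdlog: float = 1.0  # 0 gives equal baseline means
    panel_mean_factor: float = 0.2  # panel TFs are lowly expressed pre-capture
    tfs_per_program: int = 5
    targets_per_program: int = 15
    program_baseline_frac: float = 0.05  # off-cluster expression of program genes
    activation_floor: float = 0.6  # commitment switch on entering the cluster
    spike_mean: float = 0.2

    def __post_init__(self):
        if self.n_panel > self.n_genes:
            raise ConfigurationError("n_panel must not exceed n_genes")
        if self.n_spikes_on_panel > self.n_spikes:
            raise ConfigurationError("n_spikes_on_panel must not exceed n_spikes")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if self.post_depth_ratio <= 0:
            raise ConfigurationError("post_depth_ratio must be positive")
        if self.n_clusters < 1 or self.n_cells < self.n_clusters:
            raise ConfigurationError("need at least one cell per cluster")
        if self.n_clusters * self.tfs_per_program > self.n_panel:
            raise ConfigurationError("not enough panel genes for the programs")
        if (self.n_clusters * self.targets_per_program
                > self.n_genes - self.n_panel):
            raise ConfigurationError("not enough non-panel genes for targets")
        if self.branch_topology is None:
            self.branch_topology = {0: None,
                                    **{c: 0 for c in range(1, self.n_clusters)}}
        roots = [c for c, p in self.branch_topology.items() if p is None]
        if len(roots) != 1:
            raise ConfigurationError("branch_topology must have exactly one root")
        if set(self.branch_topology) != set(range(self.n_clusters)):
            raise ConfigurationError("branch_topology must cover all clusters")

    @property
    def root_cluster(self) -> int:
        return next(c for c, p in self.branch_topology.items() if p is None)

    def cluster_depths(self) -> dict[int, int]:
        depths: dict[int, int] = {}

        def depth(c: int) -> int:
            if c not in depths:
                p = self.branch_topology[c]
                depths[c] = 0 if p is None else depth(p) + 1
            return depths[c]

        for c in self.branch_topology:
            depth(c)
        return depths


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated pair of matrices."""

    cluster_of_cell: pd.Series
    latent_time: pd.Series
    true_edges: pd.DataFrame  # columns tf, target, program
    enrichment_factor: float
    expected_expression: pd.DataFrame  # genes x cells, pre-dropout means
    retained_expression: pd.DataFrame  # genes x cells, mean library composition
    panel: CapturePanel
    config: SimulationConfig


def _gene_names(config: SimulationConfig) -> tuple[list, list, list]:
    panel = [f"TF{i:04d}" for i in range(config.n_panel)]
    other = [f"G{i:05d}" for i in range(config.n_genes - config.n_panel)]
    spikes = [f"ERCC-{i:05d}" for i in range(1, config.n_spikes + 1)]
    return panel, other, spikes


def simulate_prepost(config: SimulationConfig
                     ) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Draw a paired pre-/post-capture experiment.

    Returns ``(pre, post, truth)`` with identical cell sets and orders in
    both matrices; deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel_genes, other_genes, spike_genes = _gene_names(config)
    genes = panel_genes + other_genes + spike_genes
    cells = [f"cell{i:04d}" for i in range(config.n_cells)]
    n_endo = config.n_genes
    n_total = n_endo + config.n_spikes

    # baseline expected counts per gene (log-normal heterogeneity, unit mean)
    if config.gene_mean_sdlog > 0:
        sd = config.gene_mean_sdlog
        base = config.base_mean * rng.lognormal(-sd ** 2 / 2, sd, size=n_endo)
    else:
        base = np.full(n_endo, config.base_mean)
    base[: config.n_panel] *= config.panel_mean_factor

    # cluster assignment and latent time on the branch topology
    cluster_of_cell = np.repeat(np.arange(config.n_clusters),
                                int(np.ceil(config.n_cells / config.n_clusters))
                                )[: config.n_cells]
    depths = config.cluster_depths()
    max_depth = max(depths.values())
    seg = {c: (depths[c] / (max_depth + 1), (depths[c] + 1) / (max_depth + 1))
           for c in depths}
    lo = np.array([seg[c][0] for c in cluster_of_cell])
    hi = np.array([seg[c][1] for c in cluster_of_cell])
    latent_time = rng.uniform(lo, hi)

    # cluster programs: TF hubs + targets behave like markers — near-silent
    # (program_baseline_frac) outside their cluster, activating along the
    # branch inside it (root program decays, leaf programs rise); the
    # activation is continuous across branch points
    root = config.root_cluster
    mult = np.ones((n_endo, config.n_cells))
    off = config.program_baseline_frac
    edges = []
    for c in range(config.n_clusters):
        tfs = panel_genes[c * config.tfs_per_program:
                          (c + 1) * config.tfs_per_program]
        targets = other_genes[c * config.targets_per_program:
                              (c + 1) * config.targets_per_program]
        for tf in tfs:
            for tg in targets:
                edges.append((tf, tg, c))
        members = [genes.index(g) for g in tfs + targets]
        if c == root:
            # progenitor program: declines continuously with latent time in
            # every cell, providing the shared maturation axis
            activation = 1.0 - latent_time
            mult[members, :] = off + (config.program_fc - off) * activation
        else:
            # branch program: commitment switch on entering the cluster,
            # then ramping towards the branch tip
            in_c = cluster_of_cell == c
            frac = (latent_time[in_c] - seg[c][0]) / (seg[c][1] - seg[c][0])
            floor = config.activation_floor
            activation = floor + (1.0 - floor) * frac
            mult[members, :] = off
            mult[np.ix_(members, np.where(in_c)[0])] = (
                off + (config.program_fc - off) * activation)

    mu = np.vstack([base[:, None] * mult,
                    np.full((config.n_spikes, config.n_cells),
                            config.spike_mean)])

    # shared Bernoulli dropout mask over the library composition
    p_drop = expit(config.dropout_logit_intercept
                   - config.dropout_logit_slope * np.log(mu))
    retain = rng.random(mu.shape) >= p_drop
    composition = mu * retain

    # pre-capture: NB sampling of the retained composition
    size = config.dispersion
    nb_p = size / (size + np.maximum(mu, 1e-12))
    pre_counts = rng.negative_binomial(size, nb_p) * retain

    # post-capture: multinomial resampling with the on-target boost
    boost = np.ones(n_total)
    boost[: config.n_panel] = config.enrichment_factor
    on_panel_spikes = spike_genes[: config.n_spikes_on_panel]
    for sgene in on_panel_spikes:
        boost[genes.index(sgene)] = config.enrichment_factor
    weights = composition * boost[:, None]
    lib_pre = pre_counts.sum(axis=0)
    n_post = np.rint(config.post_depth_ratio * lib_pre).astype(int)
    post_counts = np.zeros_like(pre_counts)
    for i in range(config.n_cells):
        tot = weights[:, i].sum()
        if n_post[i] == 0:
            continue
        probs = (weights[:, i] / tot if tot > 0
                 else np.full(n_total, 1.0 / n_total))
        post_counts[:, i] = rng.multinomial(n_post[i], probs)

    panel = CapturePanel(set(panel_genes), set(spike_genes),
                         set(on_panel_spikes))
    gene_meta = pd.DataFrame({
        "is_panel": [g in panel.target_genes or g in panel.spike_on_panel
                     for g in genes],
        "is_spike": [g in panel.spike_ids for g in genes]},
        index=pd.Index(genes, name="gene"))
    cell_meta = pd.DataFrame({"cluster_true": cluster_of_cell,
                              "latent_time": latent_time},
                             index=pd.Index(cells, name="cell"))
    pre = CountMatrix(genes, cells, pre_counts, cell_meta=cell_meta,
                      gene_meta=gene_meta)
    post = CountMatrix(genes, cells, post_counts, cell_meta=cell_meta,
                       gene_meta=gene_meta)
    truth = SimTruth(
        cluster_of_cell=pd.Series(cluster_of_cell, index=cells,
                                  name="cluster_true"),
        latent_time=pd.Series(latent_time, index=cells, name="latent_time"),
        true_edges=pd.DataFrame(edges, columns=["tf", "target", "program"]),
        enrichment_factor=config.enrichment_factor,
        expected_expression=pd.DataFrame(mu, index=genes, columns=cells),
        retained_expression=pd.DataFrame(mu * (1.0 - p_drop), index=genes,
                                         columns=cells),
        panel=panel,
        config=config)
    return pre, post, truth


def truth_network(truth: SimTruth) -> GeneNetwork:
    """Undirected network over the true TF->target edges (weight +1)."""
    net = GeneNetwork()
    tfs = set(truth.true_edges["tf"])
    for tf, target, _prog in truth.true_edges.itertuples(index=False):
        net.add_edge(tf, target, 1.0)
        net.graph.nodes[tf]["is_tf"] = True
        net.graph.nodes[target].setdefault("is_tf", target in tfs)
    return net


def _boost_vector(truth: SimTruth) -> np.ndarray:
    genes = truth.retained_expression.index
    boosted = truth.panel.target_genes | truth.panel.spike_on_panel
    b = np.where(genes.isin(sorted(boosted)), truth.enrichment_factor, 1.0)
    return b


def expected_on_target_fraction(truth: SimTruth, enriched: bool = True
                                ) -> pd.Series:
    """Closed-form per-cell expected on-target count fraction.

    The numerator covers panel *genes* only (spike-ins are excluded, as in
    the reported on-target metric); the denominator is the whole library.
    With ``enriched=False`` the pre-capture expectation is returned.
    """
    m = truth.retained_expression.values
    genes = truth.retained_expression.index
    is_target = genes.isin(sorted(truth.panel.target_genes)).astype(float)
    b = _boost_vector(truth) if enriched else np.ones(len(genes))
    num = (m * (b * is_target)[:, None]).sum(axis=0)
    den = (m * b[:, None]).sum(axis=0)
    return pd.Series(num / den, index=truth.retained_expression.columns,
                     name="expected_on_target")


def expected_genewise_log2_enrichment(truth: SimTruth) -> pd.Series:
    """Closed-form per-gene predicted value of the log2 CPM enrichment
    statistic log2((mean post CPM + 1) / (mean pre CPM + 1))."""
    m = truth.retained_expression.values
    b = _boost_vector(truth)
    pre_cpm = 1e6 * (m / m.sum(axis=0, keepdims=True)).mean(axis=1)
    w = m * b[:, None]
    post_cpm = 1e6 * (w / w.sum(axis=0, keepdims=True)).mean(axis=1)
    return pd.Series(np.log2(post_cpm + 1) - np.log2(pre_cpm + 1),
                     index=truth.retained_expression.index,
                     name="expected_log2_enrichment")


def truth_marker_table(truth: SimTruth) -> pd.DataFrame:
    """Reference mean-expression profile per simulated cluster ("cell type").

    Genes x types table of mean expected expression, compatible with
    :func:`capseq.cell_typing.derive_markers`.
    """
    mu = truth.expected_expression
    cols = {}
    for c in sorted(truth.cluster_of_cell.unique()):
        cells = truth.cluster_of_cell.index[truth.cluster_of_cell == c]
        cols[f"type{c}"] = mu[cells].mean(axis=1)
    return pd.DataFrame(cols)


def program_gene_sets(truth: SimTruth) -> dict[str, set]:
    """True program memberships as named gene sets (GMT-compatible)."""
    sets: dict[str, set] = {}
    for prog, sub in truth.true_edges.groupby("program"):
        sets[f"program{prog}"] = set(sub["tf"]) | set(sub["target"])
    return sets
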