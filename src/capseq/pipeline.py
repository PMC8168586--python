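"""End-to-end orchestration: simulate -> qc -> cluster/DE -> typing -> grn
-> enrichment -> pseudotime, with a summary report.

All randomness flows from a single global seed through per-stage derived
seeds (stage-name hashing), so any stage subset is reproducible on its own.
Every output file carries a metadata header with the package version, the
seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cell_typing as ct
from . import cluster_de as cd
from . import grn as grn_mod
from . import io as cio
from . import net_enrich as ne
from . import pseudotime as pt
from . import qc as qc_mod
from .simulate import (SimulationConfig, program_gene_sets, simulate_prepost,
                       truth_marker_table, truth_network)
from .types import (ConfigurationError, DataError, DEParams, GRNParams,
                    QCThresholds)

log = logging.getLogger("capseq")

STAGES = ["simulate", "qc", "cluster", "de", "typing", "grn", "enrich",
          "pseudotime"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with per-stage parameter blocks."""

    seed: int = 0
    outdir: str = "capseq_out"
    # input paths (unused when the simulate stage provides the data)
    pre_path: str | None = None
    post_path: str | None = None
    panel_path: str | None = None
    gmt_path: str | None = None
    targets_path: str | None = None
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        # desk-scale thresholds for simulated libraries; real Smart-seq2
        # libraries use the QCThresholds defaults
        "min_genes_per_cell": 200, "min_library_size": 500,
        "max_top200_fraction": 0.9, "max_spike_fraction": 0.14,
        "min_gene_mean_count": 0.05})
    cluster: dict = field(default_factory=lambda: {
        "method": "hierarchical_ward", "k_max": 6, "n_pcs": 20})
    de: dict = field(default_factory=dict)
    grn: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=lambda: {"n_perm": 200})
    pseudotime: dict = field(default_factory=lambda: {
        "n_components": 3, "n_neighbors": 15})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def _meta_header(config: PipelineConfig) -> str:
    return (f"# capseq {__version__} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig,
                 index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_header(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, stages: list | None = None,
                 outdir: str | None = None) -> dict:
    """Run the requested stages in dependency order; returns the context
    dict (matrices, tables, networks, report)."""
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ConfigurationError(f"unknown stage {s!r}")
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"report": {}}
    report = ctx["report"]

    if "simulate" in stages:
        sim_cfg = SimulationConfig(**{**config.simulation,
                                      "seed": stage_seed(config.seed,
                                                         "simulate")})
        pre, post, truth = simulate_prepost(sim_cfg)
        ctx.update(pre_raw=pre, post_raw=post, truth=truth,
                   panel=truth.panel)
        cio.write_counts(pre, out / "pre.mtx")
        cio.write_counts(post, out / "post.mtx")
        _write_table(pd.DataFrame({"cluster": truth.cluster_of_cell,
                                   "latent_time": truth.latent_time}),
                     out / "truth_cells.tsv", config, index=True)
        _write_table(truth.true_edges, out / "truth_edges.tsv", config)
        log.info("simulate: %d genes x %d cells", pre.n_genes, pre.n_cells)
    elif config.pre_path:
        ctx["pre_raw"] = cio.read_counts(config.pre_path)
        ctx["post_raw"] = cio.read_counts(config.post_path)
        ctx["panel"] = cio.read_panel(config.panel_path)

    if "qc" in stages:
        if "pre_raw" not in ctx:
            raise DataError("qc stage requires simulate output or input paths")
        th = QCThresholds(**config.qc)
        pre_f, post_f, qc_tab = qc_mod.qc_pipeline(
            ctx["pre_raw"], ctx["post_raw"], ctx["panel"], th)
        ctx.update(pre=pre_f, post=post_f, qc_table=qc_tab)
        _write_table(qc_tab, out / "qc_cells.tsv", config, index=True)
        rep = qc_mod.capture_summary(
            ctx["pre_raw"].subset_cells(pre_f.cells),
            post_f.subset_genes(ctx["pre_raw"].genes), ctx["panel"])
        ctx["capture_report"] = rep
        for k, v in rep.summary().items():
            report[f"capture_{k}"] = v
        report["cells_passing_qc"] = pre_f.n_cells
        report["genes_passing_qc"] = pre_f.n_genes
        summary = report_enrichment_summary(
            {"on_target": rep.median_on_target_pre,
             "n_expressed_panel": rep.n_expressed_panel_pre},
            {"on_target": rep.median_on_target_post,
             "n_expressed_panel": rep.n_expressed_panel_post})
        report["on_target_fold_enrichment"] = summary["fold_enrichment"]
        report["expressed_panel_increase_pct"] = summary[
            "expressed_increase_pct"]
        log.info("qc: %d cells, %d genes retained", pre_f.n_cells,
                 pre_f.n_genes)

    if "grn" in stages or "cluster" in stages or "pseudotime" in stages:
        if "pre" not in ctx:
            raise DataError("downstream stages require the qc stage")
        imputed = grn_mod.impute_capture(ctx["pre"], ctx["post"],
                                         ctx["panel"])
        ctx["imputed"] = imputed
        ctx["norm_pre"] = cd.normalize_log(ctx["pre"])
        ctx["norm_imputed"] = cd.normalize_log(imputed)

    if "cluster" in stages:
        cluster_opts = dict(config.cluster)
        res = cd.cluster_cells(ctx["norm_imputed"],
                               seed=stage_seed(config.seed, "cluster"),
                               **cluster_opts)
        ctx["clusters"] = res
        _write_table(res.labels.to_frame(), out / "clusters.tsv", config,
                     index=True)
        report["n_clusters"] = len(res.clusters())
        log.info("cluster: %d clusters", len(res.clusters()))

    if "de" in stages:
        if "clusters" not in ctx:
            raise DataError("de stage requires the cluster stage")
        params = DEParams(**config.de)
        tables = cd.de_one_vs_rest(ctx["norm_imputed"],
                                   ctx["clusters"].labels, params)
        ctx["deg_tables"] = tables
        ctx["clusters"].deg_tables = tables
        for name, tab in tables.items():
            _write_table(tab, out / f"deg_{name}.tsv", config)
        report["n_significant_degs"] = int(sum(
            t["significant"].sum() for t in tables.values()))
        log.info("de: %d comparisons", len(tables))

    if "typing" in stages:
        if "deg_tables" not in ctx or "truth" not in ctx:
            raise DataError("typing stage requires de output and a reference")
        profiles = truth_marker_table(ctx["truth"])
        markers = ct.derive_markers(profiles)
        universe = set(ctx["norm_imputed"].index)
        degs = {name.split("_vs_")[0]:
                set(t.loc[t["significant"] & (t["ln_fc"] > 0), "gene"])
                for name, t in ctx["deg_tables"].items()}
        typing = ct.score_cluster_types(degs, markers, universe)
        ctx["typing"] = typing
        _write_table(markers.to_frame(), out / "markers.tsv", config)
        _write_table(typing, out / "typing.tsv", config)
        report["n_typed_clusters"] = int(
            (typing.groupby("cluster")["fdr"].min() <= 0.05).sum())
        log.info("typing: %d cluster/type pairs", len(typing))

    if "grn" in stages:
        gparams = GRNParams(**config.grn)
        tf_genes = ctx["panel"].target_genes
        degs_all: set = set()
        if "deg_tables" in ctx:
            for t in ctx["deg_tables"].values():
                degs_all |= set(t.loc[t["fdr"] <= 0.05, "gene"])
        subset = sorted((degs_all | tf_genes)
                        & set(ctx["norm_imputed"].index)) or None
        pre_subset = (sorted((degs_all | tf_genes) & set(ctx["norm_pre"].index))
                      or None)
        net_pre = grn_mod.build_network(ctx["norm_pre"], gparams,
                                        genes=pre_subset, tf_genes=tf_genes)
        net_imp = grn_mod.build_network(ctx["norm_imputed"], gparams,
                                        genes=subset, tf_genes=tf_genes)
        ctx.update(net_pre=net_pre, net_imputed=net_imp)
        cio.write_network(net_pre, out / "network_pre.tsv")
        cio.write_network(net_imp, out / "network_imputed.tsv")
        _write_table(net_imp.node_table(), out / "nodes_imputed.tsv", config)
        report.update(
            network_pre_nodes=net_pre.n_nodes, network_pre_edges=net_pre.n_edges,
            network_imputed_nodes=net_imp.n_nodes,
            network_imputed_edges=net_imp.n_edges)
        if "deg_tables" in ctx:
            comp_cluster = {name: name.split("_vs_")[0]
                            for name in ctx["deg_tables"]}
            sub = grn_mod.cluster_subnetworks(
                net_imp, ctx["deg_tables"], comp_cluster, tf_genes, gparams)
            ctx["subnetworks"] = sub
            cio.write_network(sub, out / "network_clusters.tsv")
            _write_table(sub.node_table(), out / "nodes_clusters.tsv", config)
        log.info("grn: pre %d/%d, imputed %d/%d nodes/edges",
                 net_pre.n_nodes, net_pre.n_edges, net_imp.n_nodes,
                 net_imp.n_edges)

    if "enrich" in stages:
        if "net_imputed" not in ctx:
            raise DataError("enrich stage requires the grn stage")
        n_perm = int(config.enrich.get("n_perm", 200))
        tf_genes = ctx["panel"].target_genes
        for name in ("pre", "imputed"):
            net = ctx[f"net_{name}"]
            if net.n_edges and (set(net.nodes()) & tf_genes):
                res = ne.nea(net, tf_genes, n_perm=n_perm,
                             seed=stage_seed(config.seed, "enrich"))
                report[f"nea_{name}_observed"] = res.observed
                report[f"nea_{name}_z"] = res.z
                report[f"nea_{name}_p"] = res.p
        if "truth" in ctx:
            gmt = (cio.read_gene_sets(config.gmt_path) if config.gmt_path
                   else program_gene_sets(ctx["truth"]))
            if "subnetworks" in ctx and ctx["subnetworks"].n_nodes:
                nodes = ctx["subnetworks"].node_table()
                subnet_genes = {c: set(g["gene"])
                                for c, g in nodes.groupby("cluster")}
                tab = ne.tfppi_enrichment(subnet_genes, gmt,
                                          set(ctx["net_imputed"].nodes()))
                ctx["tfppi"] = tab
                _write_table(tab, out / "tfppi_enrichment.tsv", config)
            targets = set(map(tuple, ctx["truth"].true_edges[
                ["tf", "target"]].itertuples(index=False)))
            target_genes = {t for _, t in targets}
            universe = set(ctx["norm_imputed"].index)
            _, p_fisher, _ = ne.fisher_target_enrichment(
                set(ctx["net_imputed"].nodes()), target_genes, universe)
            report["fisher_target_p_imputed"] = p_fisher
        log.info("enrich: done")

    if "pseudotime" in stages:
        if "clusters" not in ctx:
            raise DataError("pseudotime stage requires the cluster stage")
        opts = dict(config.pseudotime)
        coords = pt.diffusion_map(ctx["norm_imputed"],
                                  seed=stage_seed(config.seed, "pseudotime"),
                                  **opts)
        labels = ctx["clusters"].labels
        if "truth" in ctx:
            # start cluster: the label most enriched in root-cluster cells
            truth = ctx["truth"]
            root_cells = truth.cluster_of_cell[
                truth.cluster_of_cell == truth.config.root_cluster].index
            overlap = labels.reindex(root_cells).dropna()
            root_label = (overlap.mode().iloc[0] if len(overlap)
                          else labels.iloc[0])
        else:
            root_label = labels.iloc[0]
        traj = pt.fit_lineages(coords, labels, root_label)
        ctx["trajectory"] = traj
        _write_table(coords, out / "coords.tsv", config, index=True)
        _write_table(traj.pseudotime, out / "pseudotime.tsv", config,
                     index=True)
        report["n_lineages"] = len(traj.lineages)
        report["root_cluster_label"] = root_label
        log.info("pseudotime: %d lineages", len(traj.lineages))

    report_df = pd.DataFrame(sorted(report.items()),
                             columns=["metric", "value"])
    _write_table(report_df, out / "report.tsv", config)
    return ctx


def report_enrichment_summary(pre_report: dict, post_report: dict) -> dict:
    """Derived capture-benefit summary from matched pre/post reports.

    ``fold_enrichment`` is the post/pre ratio of the on-target fraction
    (``None``-flagged when the pre fraction is zero);
    ``expressed_increase_pct`` is the percent increase in expressed panel
    genes.  Display values are rounded to the nearest integer.
    """
    pre_frac = float(pre_report["on_target"])
    post_frac = float(post_report["on_target"])
    n_pre = float(pre_report["n_expressed_panel"])
    n_post = float(post_report["n_expressed_panel"])
    fold = post_frac / pre_frac if pre_frac > 0 else None
    pct = 100.0 * (n_post - n_pre) / n_pre if n_pre > 0 else None
    return {
        "fold_enrichment": fold,
        "fold_enrichment_display": None if fold is None else round(fold),
        "expressed_increase_pct": pct,
        "expressed_increase_pct_display": None if pct is None else round(pct),
        "undefined": pre_frac == 0 or n_pre == 0,
    }
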