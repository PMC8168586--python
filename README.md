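# capseq

Analysis of **paired pre-/post-capture single-cell RNA-seq**: the setting
in which the same single-cell libraries are sequenced before and after
hybridization-capture enrichment of a gene panel — typically ~1000
transcription factors (TFs), which carry much of the information about
cell identity and differentiation but are lowly expressed and heavily
dropped out in standard scRNA-seq.

The package is for computational biologists who have paired gene×cell
count matrices (plus a panel gene list) and want to quantify what capture
bought them and to exploit it downstream:

* **QC and capture metrics** — four-rule cell filtering on the pre-capture
  matrix (detected genes, library size, top-200 complexity, spike-in
  fraction), gene filtering by mean count, per-cell on-target fractions,
  per-gene enrichment log2((mean post CPM + 1)/(mean pre CPM + 1)), and
  detected-TFs-per-cell statistics.
* **Clustering and differential expression** — log2(count/size factor + 1)
  normalization, Ward/Louvain clustering on a PCA embedding, Wilcoxon
  rank-sum DE (exact null for small groups) with BH FDR; significance at
  FDR ≤ 0.05 and |ln fold change| ≥ 0.5.
* **Marker-based cell typing** — unique marker derivation from reference
  profiles (twofold exclusion rule) and hypergeometric cluster↔type
  scoring.
* **Imputed gene-regulatory networks** — the pre-capture transcriptome
  extended by panel-gene rows taken from post-capture and rescaled per cell
  by the library-size ratio; coexpression edges at |Pearson r| > 0.8 with
  BH-significant correlation; cluster subnetwork extraction (≥50%-expressed
  up-regulated DEGs, highest-lnFC assignment, ≥20% TF-neighbor rule,
  ≥3-node components).
* **Network enrichment analysis (NEA)** — connectivity of a gene set
  against degree-preserving edge-swap permutations, plus Fisher 2×2 target
  enrichment, hypergeometric TF-PPI term enrichment, and the exact
  Wilcoxon signed-rank paired comparison.
* **Pseudotime** — diffusion maps with local kernel bandwidths, MST
  lineages from a designated start cluster, projection-based pseudotime in
  [0, 1], and smoothed expression-vs-pseudotime profiles.
* **Synthetic paired-capture generator** — cluster-structured zero-inflated
  negative-binomial counts on a branching latent trajectory with a known
  TF→target network, ERCC-like spike-ins and a multinomial capture
  operation with enrichment factor E; every downstream claim is testable
  against its ground truth and closed-form expectations.

## Worked example

Run the whole pipeline on a simulated experiment (300 cells, 2000 genes,
150-gene TF panel, enrichment factor 100, 4× post-capture depth):

```python
from capseq import PipelineConfig, run_pipeline

ctx = run_pipeline(PipelineConfig(seed=1, outdir="capseq_out"))
for k, v in ctx["report"].items():
    print(k, v)
```

Selected output (also written to `capseq_out/report.tsv`):

```
capture_median_on_target_pre    0.007966486156445353
capture_median_on_target_post   0.4450316524400886
on_target_fold_enrichment       55.86297944923082
capture_n_expressed_panel_pre   104
capture_n_expressed_panel_post  124
expressed_panel_increase_pct    19.23076923076923
capture_mean_expression_r       0.9711160815884442
n_clusters                      3
network_pre_nodes               144
network_pre_edges               42
network_imputed_nodes           210
network_imputed_edges           85
n_lineages                      2
```

Reading this: capture lifted the median share of panel-gene counts from
0.8% to 44.5% (a 56-fold enrichment), 20 additional panel TFs became
detectable (+19%), and pre/post mean expression stayed highly correlated
(r = 0.97), i.e. enrichment preserved relative abundances.  Clustering on
the imputed matrix recovers the three simulated populations; the imputed
coexpression network has ~1.5× the nodes and ~2× the edges of the
pre-capture network; and the trajectory stage finds the two simulated
branches from the root cluster.

The same stages are available from the shell:

```bash
capseq run-all --seed 1 --outdir capseq_out
capseq qc --config my_config.yaml        # any stage runs its upstream deps
```

On real data, set `pre_path`/`post_path`/`panel_path` in the YAML config
(Matrix Market + gene/cell TSVs, or dense TSV) and omit the simulate stage.

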