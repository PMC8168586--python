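# Methods

`capseq` analyses paired measurements of the same single cells before and
after hybridization-capture enrichment of a gene panel (typically ~1000
transcription factors).  This note records the models and procedures each
stage implements, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Quality control and capture metrics

Cells are filtered on the **pre-capture** matrix by four rules, and the
surviving cell set is applied to the post-capture matrix: at least
`min_genes_per_cell` detected non-spike genes (default 2000), library size
at least `min_library_size` (default 5×10⁵; total counts stand in for
mapped read pairs since alignments are out of scope), the 200 most
expressed genes of the cell holding at most `max_top200_fraction` of its
counts (default 0.50; ties in the within-cell ranking break by gene order),
and spike-ins at most `max_spike_fraction` of counts (default 0.14).  Genes
are kept when their mean count over cells is strictly greater than
`min_gene_mean_count` (default 1).  The defaults suit real full-length
single-cell libraries; the bundled pipeline configuration scales them down
for the desk-scale generator (200 genes, 500 counts, top-200 share 0.9).

Capture performance metrics:

* **on-target fraction** per cell: counts on panel genes / library size
  (spike-ins excluded from the numerator);
* **gene-wise enrichment**: log2((mean post CPM + 1)/(mean pre CPM + 1));
* **detected panel genes** per cell: raw count > 0 ("expressed" panel genes
  are those with non-zero mean counts);
* **mean-expression correlation**: Pearson r between log2(mean CPM + 1) of
  panel genes pre vs post, over genes expressed in either matrix.  The CPM
  scale is used because mean raw counts differ by the 4× depth ratio.

The derived summary reports the post/pre fold change of the on-target
fraction and the percent increase in expressed panel genes, rounded to
integers for display.

## Normalization, clustering, differential expression

Expression values are log2(count / size factor + 1); the default size
factor is library size over the median library size (a DESeq-style
median-ratio factor is available).  Clustering operates on the top 20
principal components of z-scored log expression restricted to the 500 most
variable genes (restricting to highly variable genes is standard practice
and is what makes the embedding reflect biology rather than sampling
noise).  The default algorithm is Ward agglomeration with the number of
clusters chosen by maximal mean silhouette over k ∈ [2, k_max] (ties toward
smaller k); Louvain communities on a kNN graph are available as an
alternative.

Differential expression uses a two-sided Wilcoxon rank-sum test per gene.
The exact null distribution (dynamic programming over doubled mid-ranks, so
ties are handled exactly) is used when both groups have ≤ 25 cells; larger
groups use the tie-corrected normal approximation with continuity
correction.  Constant genes get p = 1 by convention.  P-values are BH
adjusted over the tested genes.  The fold change is the natural log of
(mean + 1) ratios on the de-logged normalized scale; significance requires
FDR ≤ 0.05 and |lnFC| ≥ 0.5 by default.  Two-sided exact p-values double
the smaller tail and cap at 1.

## Cell typing

Reference profiles are consumed as a mean-expression-per-type table.  A
gene is a marker candidate for the type where it is most expressed, is
discarded when any other type expresses it above own-type/`fold_cutoff`
(default 2), and marker sets are pairwise disjoint by construction.  When
replicate-level reference significance calls exist they can be supplied as
candidate sets; from a bare mean table an FDR step is not computable, so
the argmax rule is the default candidate filter.  Cluster DEG sets are
scored against marker sets with an upper-tail hypergeometric test
(N = universe, K = markers, n = DEGs, k = overlap) and BH correction over
all (cluster, type) pairs.

## Imputed gene-regulatory networks

The imputed matrix replaces each panel gene's pre-capture row by its
post-capture row rescaled per cell by pre-library/post-library (replacement
rather than averaging: post-capture is strictly more sensitive for panel
genes; per-cell rescaling is the only choice that preserves within-cell
composition).  Panel genes absent from pre but expressed post are appended
as new rows; panel genes silent in post keep their pre values.  Imputed
values are fractional.

Networks connect gene pairs with |Pearson r| > 0.8 on log-normalized
values *and* BH-adjusted correlation p ≤ 0.05 (t-approximation on n − 2
degrees of freedom; at realistic cell numbers the |r| cutoff dominates).
Zero-variance genes are excluded and recorded.  Cluster subnetworks follow
four rules: up-regulated DEGs (FDR ≤ 0.05, expressed in ≥ 50% of cluster
cells) are candidates; genes significant for several clusters go to the
cluster of highest lnFC; panel TFs qualifying under the same rule are
cluster TFs; TFs with ≥ 20% of network neighbors in a cluster's DEG set
attach to that cluster (highest fraction on ties); finally connected
components smaller than 3 nodes are dropped.

## Network enrichment analysis

The NEA statistic is the number of edges with at least one endpoint in the
gene set; the null is sampled by degree-preserving double edge swaps (10
swap attempts per edge per permutation).  The sampler draws two edges
uniformly and one of the two rewirings at random, rejecting self-loops and
duplicates, so the chain is symmetric and its stationary distribution is
uniform over simple graphs with the fixed degree sequence — a property the
enumeration-based calibration test requires and that degree-biased edge
selection would violate.  Empirical p uses the add-one rule,
(1 + #{null ≥ obs})/(1 + n); z is flagged undefined when the null is
degenerate.  Note a structural property of this statistic: the summed
degree of the gene set is invariant under degree-preserving permutation, so
the statistic varies only through within-set edges; a set whose members
interconnect more than chance therefore shows *fewer* incident edges than
its null.  The statistic is isolated behind `incident_edge_count` and can
be swapped.

Auxiliary statistics: Fisher's exact test on 2×2 tables of network
membership × target status (or a two-network comparison); hypergeometric
TF-PPI term enrichment with BH within cluster; exact two-sided Wilcoxon
signed-rank comparison of paired per-term gene counts (zeros dropped,
average ranks, exact by DP for ≤ 25 non-zero pairs).  TF→target evidence
filters keep weight-based links at weight ≥ 0.1 (inclusive) and
coexpression links at p < 10⁻⁷ (strict), unioned and deduplicated.

## Pseudotime

The diffusion map uses a Gaussian kernel with per-cell local bandwidths
(distance to the ⌈n_neighbors/2⌉-th neighbor, default n_neighbors = 15),
density normalization, and row normalization to a Markov matrix solved
through its symmetric conjugate; coordinates are the leading non-trivial
eigenvectors scaled by eigenvalues.  Signs are fixed by making the
largest-magnitude loading positive — unlike a first-nonzero rule this is
invariant to cell order, which the permutation-equivariance property
requires.  Lineages are root-to-leaf paths of the Euclidean minimum
spanning tree over cluster centroids in diffusion space; per-cell
pseudotime is the normalized arc length of the orthogonal projection onto
the piecewise-linear centroid path (principal-curve smoothing is
deliberately replaced by this deterministic, testable approximation).
Cells attach to their nearest tree-edge segment and belong to every
lineage through that edge with equal weights.  Expression-vs-pseudotime
profiles are centered rolling means over pseudotime-ordered cells;
window = 1 reproduces the raw ordering.

## Synthetic study conditions

The generator emulates a paired capture experiment at desk scale.
Defaults (chosen once as the package's study conditions):

| parameter | default | meaning |
|---|---|---|
| n_cells / n_genes / n_panel | 300 / 2000 / 150 | matrix scale; panel ≈ 7.5% of genes |
| n_clusters | 3 | root + two leaves (branching topology) |
| base_mean / gene_mean_sdlog | 2 / 1 | log-normal gene means, counts per expressed gene |
| panel_mean_factor | 0.2 | panel TFs are lowly expressed pre-capture |
| dispersion | 3 | NB size; var = μ + μ²/size |
| program_fc | 4 | peak fold effect of a cluster program |
| program_baseline_frac | 0.05 | off-cluster expression of program genes |
| activation_floor | 0.6 | commitment switch on entering a branch |
| enrichment_factor | 100 | on-target probability multiplier E |
| post_depth_ratio | 4 | post/pre library size ratio |
| n_spikes / on panel | 92 / 56 | ERCC-like constant-mean controls |
| dropout slope / intercept | 4 / −2.5 | logit of extra zero-inflation vs ln mean |

Each cluster carries a program of 5 panel-TF hubs and 15 targets; the
TF×target pairs are the ground-truth edges.  The root program is a
progenitor program that decays continuously with latent time in every cell
(the shared maturation axis that makes the branching geometry recoverable);
leaf programs switch on at branch entry and ramp toward the tip.  Dropout
is a per-(gene, cell) Bernoulli mask on the cell's library composition,
steeply dependent on the expected mean, and *shared* between the pre and
post draws: pre-capture counts are NB draws times the mask, post-capture
counts are a multinomial over the masked composition with panel genes (and
on-panel spikes) multiplied by E and the depth scaled by the post/pre
ratio.  Capture therefore rescues sampling zeros but not transcripts the
library never contained, and at E = 1 with equal depth the pre and post
matrices are exchangeable.  All closed-form expectations (on-target
fraction, per-gene enrichment) follow from this construction and are
exposed for testing.

What the generator does **not** emulate: amplification/PCR duplication,
batch effects beyond cluster programs, read-level structure (positional
coverage, splice junctions), gene–gene correlation beyond the shared
program activations, and probe-specific capture efficiency variation.
Passing recovery tests on these conditions therefore demonstrates that the
pipeline's inference machinery is correct under its own generative
assumptions, not that real libraries satisfy those assumptions.

## Numerical conventions and degenerate inputs

Deterministic behavior under a global seed: per-stage seeds derive from the
stage name (CRC32 hashing, kept below 2³¹), so stage subsets reproduce.
Order stability: gene and cell order is preserved by all subsetting;
cluster labels are renumbered by first appearance; silhouette ties break
toward smaller k; marker ties (a gene equally highest in two types) drop
the gene.  Zero libraries are errors for normalization and imputation and
yield missing values for per-cell fractions.  Empty QC results, unknown
roots, windows larger than the cell count and degenerate (all-identical)
diffusion inputs raise typed errors (`DataError`/`ConfigurationError`).

## Known limitations

* Raw Pearson on log-normalized values is a conservative reading of the
  |r| > 0.8 rule; correlation transforms used by pooling-based tools can
  admit more edges at equal thresholds.
* The projection-based pseudotime assigns boundary cells of the root
  cluster a clamped pseudotime of 0 (the root centroid anchors the path).
* The hierarchical clustering path recomputes the full linkage per
  candidate k; fine at thousands of cells, not tuned for 10⁵ cells.
* Marker derivation from a bare mean-expression table cannot apply a
  reference-level FDR filter; supply candidate sets when replicate-level
  calls are available.
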