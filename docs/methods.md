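# Methods

This note documents the models and procedures `myelotax` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions the code commits to.

## Data model and normalization

Counts are held as a cells × genes `AnnData` with integer sparse `.X` and
per-cell metadata (`sample`, `condition`, `region`, `species`, `cell_type`)
in `.obs`. On disk the 10x convention is used: genes × cells MatrixMarket
plus `features.tsv`/`barcodes.tsv` and a metadata CSV.

Quality control removes cells failing any active rule; three presets cover
the supported modalities: single-nucleus data (≥500 detected genes, ≤10%
mitochondrial content, doublets dropped), targeted spatial panels (≥5
features and ≥10 counts), and genome-wide binned spatial data (≥5 features,
≤75% mitochondrial content). The mitochondrial predicate is a configurable
prefix rule (`MT-` human, `mt-` mouse); ribosomal exclusion for DEG testing
uses case-insensitive `RPS`/`RPL` prefixes. QC is idempotent, and removal
counts per rule are reported.

Normalization is library-size log-scaling, `ln(1 + x / total × 10,000)`.
Z-scoring of aggregate profiles uses the population SD (÷n); this convention
is fixed so that closed-form test values are stable, and zero-variance genes
are dropped and reported rather than silently producing NaN.

## Differential expression

`wilcoxon_deg` tests each gene with a two-sided Wilcoxon rank-sum via the
normal approximation with average ranks, tie correction, and continuity
correction (vectorized across genes). Groups with fewer than 3 cells on
either side are skipped with a warning. Fold changes are
`log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))` — pseudocount 1 on
the de-logged means, the convention of the mainstream single-cell toolkits.
BH adjustment is applied within each group's test family. The asymptotic
path is used at all sample sizes (rather than switching to an exact
enumeration for tiny groups) so that p-values are a single continuous
function of the data; the test suite validates it against a from-scratch
rank-sum computation including ties.

## Graph construction and Paris clustering

Cells are embedded by PCA (default 30 components) of the per-gene
standardized log-normalized matrix. The cell graph is a shared-nearest-
neighbor graph: each cell's neighbor set is itself plus its k = 20 nearest
others; an edge's weight is the Jaccard overlap of the two sets, and edges
below 1/15 are pruned. These defaults mirror the widely used
nearest-neighbor-graph construction in the Seurat ecosystem, from which the
1/15 prune value originates.

Paris agglomerates the graph under the node-pair sampling distance
`d(a,b) = p(a)p(b)/p(a,b)`: at each step the connected pair with minimal
distance merges, with exact ties broken toward the lexicographically
smallest cluster-id pair for full determinism. The implementation keeps a
lazy min-heap over live inter-cluster edges; every pushed entry is valid
exactly while both endpoint clusters are alive, so no stale-entry
re-validation is needed. Disconnected components are clustered independently
and concatenated under an infinite-height root (the Paris distance is
undefined across zero-weight pairs); Newick serialization caps those heights
at twice the largest finite height. The test suite proves merge-sequence
equality with an exhaustive O(n³) re-computation oracle on 100 random
connected graphs.

Cutting supports an exact cluster count or a largest-relative-height-gap
heuristic. Labels are numbered along dendrogram leaf order.

## Weak-cluster merging

After cutting, a cluster is merged into its nearest dendrogram sibling when
it has fewer than `min_cells` (default 20) cells, or fewer than `min_degs`
(default 5) genes passing `p_adjusted < 0.05` and `|log2FC| ≥ 0.25` against
that sibling; the procedure iterates to a fixed point (cluster count
strictly decreases, so it terminates) and logs every merge. The sibling of a
cluster is found by replaying the merge list: the first merge uniting its
leaves with another cluster's leaves defines the sibling; if that merge
joins several clusters at once, the one nearest in leaf order is taken.
These thresholds are deliberate, configurable stand-ins — "enough DEGs" and
"very small" have no canonical values — and are documented as such. A
caveat worth knowing: halves of a *data-driven* split legitimately differ on
the genes that drove the split (a selection effect), so the DEG criterion
dissolves arbitrary/noise splits but correctly preserves splits that track
real expression axes.

## Signature scoring and the taxonomy

The per-cell module score ranks a cell's genes by expression (descending,
average ranks for ties), truncates ranks at `r_max + 1` (default
`r_max = 1500`, the canonical default of rank-based single-cell signature
scoring), and maps the Mann–Whitney U′ statistic of the module's ranks to
`[0, 1]`. The score is invariant to any monotone transform of the cell's
expression vector. Genes missing from a dataset (restricted spatial panels)
are dropped from the module and n_g shrinks accordingly; empty modules are
skipped with a record.

Dominant modules per cell use the argmax of per-module z-scaled scores
(z-scaling across all scored cells; a flag could restrict scaling within
cell type, but cross-cell scaling is the default because supercluster
assignment is performed within one cell type anyway). Cluster → supercluster
classification takes the module with the highest mean scaled score across
the cluster's cells — a score-level reading of "most enriched module" — and
reports the margin to the runner-up; margins near zero mark mixed or
weak-signal clusters whose label should not be over-interpreted. Ties in
any argmax resolve lexicographically.

The condition level labels a cluster `Non-homeostasis` when the fraction of
its cells from non-homeostatic samples is ≥ 0.5 (exact ties flagged); the
threshold is conservative toward flagging activation. The four-level tree
carries, per cluster, the cell count, condition composition, and a Gini
coefficient over the cluster's condition-normalized share vector (counts
divided by total cells per condition, so abundant conditions do not dominate).

## Composition statistics

* Gini: `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ)`, scale-invariant, 0 for equal shares,
  `1 − 1/k` for a single nonzero among k.
* Enrichment: upper-tail hypergeometric `P(X ≥ k)` with fold =
  observed/expected; the population is the compared cell universe and is
  configurable per analysis. BH correction over each test family.
* Cluster diversity: `n_clusters ~ condition + log(n_nuclei)` with a
  Poisson log link. The log-nuclei covariate absorbs sampling depth; when it
  is constant across records it is dropped (it would be collinear with the
  intercept). Pearson-residual dispersion above 1.5 triggers a negative
  binomial refit with MLE dispersion. The rate ratio is
  `exp(β_condition)` with a two-sided Wald p; no multiplicity correction is
  applied to the single global contrast. An optional random intercept
  (region or patient) is available through a variational-Bayes mixed Poisson
  model; it is OFF by default because the approximate posterior is not
  exactly reproducible across BLAS builds and the fixed-effects fit is the
  deterministic reference path.

## Spatial mapping

Cluster signatures are derived by one-vs-rest Wilcoxon on the genes shared
with the spatial panel, after normalizing on the full reference library —
normalizing *before* restricting the gene space prevents panel restriction
from manufacturing compositional fold changes. Per cluster, the top 20
(configurable within 10–30) up-regulated genes with `p_adjusted < 0.05` are
kept, ordered by descending log2FC; clusters retaining fewer than 3 genes
are declared non-imputable. Spatial cells of the target identity get the
argmax raw signature score over cluster signatures (scored globally, not per
FOV); `r_max` defaults to `min(1500, panel size)`. Supercluster labels are
inherited through the reference cluster → supercluster map. Module feature
maps sum module-gene counts over target cells (others fixed at zero),
z-score across all cells, and clip to [−1, +1]; a zero-variance map returns
zeros with a warning.

## Neighborhood interaction networks

Neighbors are all cells within 100 µm (boundary inclusive — the convention
is fixed for determinism); identities with fewer than 3 cells are removed
first. The directed interaction proportion A→B pools B-neighbor counts over
all A cells, divides by total neighbors of A cells, then by `N_A × N_B`, and
scales to percent. The abundance normalization is implemented literally as
stated by its source even though it makes values abundance-dependent; the
raw pooled fraction is available alongside for interpretability. The
undirected network averages the two directed proportions, carries node sizes
as cell counts, and reintroduces zero-edge identities so the identity
palette stays complete. Coordinates are converted to µm by an explicit
`unit_scale` factor rather than any auto-detection heuristic. All outputs
are invariant to cell order, translation, and rotation.

## Nucleus reconstruction from binned spots

Segmentation polygons (GeoJSON, µm, image convention with y increasing
downward) are repaired if invalid and dilated by a 2 µm buffer (64 segments
per full circle, keeping circle-area error under 1% at the scales tested).
Each spot center covered by exactly one dilated polygon is assigned to that
nucleus; centers covered by two or more are dropped; on-boundary centers
count as inside. Counts are summed per nucleus per gene; empty nuclei stay
as all-zero rows; both original and dilated areas are stored (dilated is the
default downstream column). Transcript conservation
(assigned + dropped + unassigned = input) holds at every stage and is
asserted in tests. Multi-assignment is evaluated after dilation, matching
the stated order of operations of the source pipeline.

## Cross-species comparison

Ortholog tables are classified into one-to-one / one-to-many / many-to-many
from their own multiplicities; the default merge strategy keeps only
one-to-one pairs (a keep-all strategy exists) and renames the source species
into the target namespace before intersecting gene spaces (floor: 50 shared
genes). Aggregate per-group profiles (z-scaled log-normalized means by
default) are correlated pairwise with two-sided tests. Bootstrap stability
resamples 80% of shared genes without replacement for 1,000 iterations and
reports the fraction of iterations with `|r_boot| ≥ |r_obs|`. This follows
its source definition literally, with the documented caveat that it is a
*stability* measure (1 = stable), not a null-hypothesis p-value: a pair with
r_obs ≈ 0 is trivially "stable", and a strong-but-imperfect correlation
hovers near 0.5 because bootstrap replicates scatter symmetrically around
the observed value; only exactly degenerate profiles (r = ±1) reach 1.
Cross-species flow tables equalize species contributions by downsampling the
larger species with largest-remainder rounding (preserving native cluster
proportions within ±1 cell), then emit links between native labels bridged
through a caller-provided joint co-embedding label:
`share(a,b) = Σⱼ P(a|j) P(b|j) P(j)`, suppressing links below 1%. The
co-embedding itself (an integration step) is outside this package's scope;
any joint labeling can be supplied.

## Synthetic data: what it emulates, and what it does not

The generator produces the three input modalities with planted ground truth:

* **Counts**: negative-binomial (mean/size parameterization, "dispersion" =
  size) gene × cell matrices where each program's module genes are elevated
  `fold_change`-fold over a flat `baseline_mean`. Defaults — 150 cells per
  program, fold 8, baseline 0.5, size 2, 300 background genes — give
  per-cell depths and detection rates in the range of shallow single-nucleus
  data while keeping the demo and test suite fast on one CPU. Program
  metadata (condition/region/species) follows a configurable plan.
* **Spatial scenes**: uniform or Gaussian-clustered point patterns of typed
  cells in a µm field, with optional minimum separation via bounded dart
  throwing.
* **Binned scenes**: transcripts placed uniformly inside circular/polygonal
  nuclei and snapped to the nearest 2 µm grid spot, with the per-nucleus
  truth matrix returned; snapping can push a spot just outside its source
  polygon, which is exactly the border case the 2 µm dilation absorbs.

All generators are pure functions of (spec, seed); the top-level seed is
split per sub-generator with `SeedSequence` so partial reruns reproduce.

Deliberately not emulated: ambient RNA, doublets, batch effects, gene–gene
correlation beyond the planted programs, segmentation errors, and spatially
varying detection efficiency. Passing tests therefore demonstrate
correctness of the statistics and recovery under the planted model — not
robustness to those real-data artifacts. One emergent property *is*
realistic and worth knowing when reading recovery numbers: cells that draw
few counts on their program's module genes (likely for small modules, e.g. a
3-gene proliferation program) are genuinely unidentifiable, and tend to pool
into mixed weak-signal clusters whose classification margin is ≈ 0 — the
margin, not the label, is the informative output for such clusters.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the demo pipeline
(`examples/pipeline.yaml`: 8 programs × 150 cells, 300 background genes,
spatial scene with 320 typed cells, 4-nucleus binned scene, 40 GLM records)
runs end-to-end in a few seconds on one CPU and reproduces byte-identical
CSV/JSON artifacts across reruns at a fixed seed (checksummed in
`manifest.json`; the manifest's own timing fields are excluded from the
comparison). CSV floats are written with a fixed `%.10g` format to keep
checksums stable. These sizes were chosen as the smallest configuration
that exercises every stage with comfortable statistical margins.

## Known limitations

* The merge step's DEG thresholds are stand-ins for unquantified published
  defaults; conclusions about cluster granularity should be checked against
  a sensitivity sweep of `min_cells`/`min_degs`.
* The Paris implementation targets desk-scale graphs (≈10⁴ nodes); it is
  O(m log m) in pushed heap entries but pure Python, not a compiled kernel.
* The bootstrap stability statistic inherits the non-monotonicity of its
  literal definition (see above).
* Random-effect GLMs use a variational approximation; for publication-grade
  mixed models refit externally.
* The imputation scores are computed globally, not per FOV; panels with
  strong FOV-level depth differences may warrant per-FOV scaling.
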