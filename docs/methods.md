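# Methods

## The score

For cells described by binned copy-number profiles and grouped by sample of
origin, the Spatial Heterogeneity score is the mean silhouette value computed
with L1 (Manhattan) distances and the samples as clusters. L1 is used because
low-order norms discriminate near from far neighbours better than Euclidean
distance at the dimensionality of binned CN profiles (hundreds to thousands
of bins). Distances are computed on the values exactly as loaded — no
rounding, no scaling — so the score is agnostic to whether a caller emits
integer states or fractional estimates; the score is invariant under positive
scaling of the whole matrix because it is a ratio of distances.

Conventions for degenerate cells: a cell alone in its block gets sh = 0
(the standard silhouette convention), as does a cell with a = b = 0 (an
exact duplicate present in two blocks); both conventions keep the score
well-defined without discarding cells. `b(p)` is the minimum over *blocks*
other than the cell's own block of the mean distance to that block.

The score is the unweighted mean over all cells of the pooled dataset, so
unbalanced samples weight the score by their cardinality; we keep the plain
mean rather than a per-block mean of means because the per-cell average is
the definition that the silhouette analogy and the downsampling-robustness
experiment both rest on.

The partition scan evaluates **all** set partitions of the sample labels
into ≥ 2 blocks (Bell(n) − 1 of them), not only one-vs-rest merges, so the
best grouping of, say, five sections is found even when two disjoint pairs
are each clonally related. Enumeration is capped at 6 samples (203
partitions) unless explicitly overridden. The cell × cell distance matrix is
computed once per scan; each partition is then scored from per-sample
distance sums in O(n_cells × n_samples), so the scan's cost is dominated by
the single distance computation. The full matrix is materialised
(8 bytes × n²); up to ~20k cells this fits comfortably in a few GB, beyond
that compute distances blockwise and pass them in via `distances=`.

Scores ≥ 0.2 are annotated "segregated" and lower scores "well-mixed" in
outputs, a rule of thumb derived from the simulation studies; it has no
effect on any computation and should not be read as a clinically validated
threshold.

## Preprocessing

Ploidy is the bin-length-weighted mean copy number; caller-supplied ploidy
annotations take precedence when given. MAD is the unscaled
`median(|x − median(x)|)` of a cell's profile, a noise proxy for
amplification artefacts and S-phase cells. Filtering removes cells with
ploidy inside the closed interval [1.6, 2.9] (diploid and pseudo-diploid
cells carry no CNA signal in a tumor analysis), then cells whose MAD
strictly exceeds the 95th percentile — linear interpolation between order
statistics — of the MADs of the *surviving* cells, so noisiness is judged
relative to the tumor-cell population. A flag computes the percentile over
all input cells instead; both the ordering and the interpolation rule are
fixed and documented because different conventions move the cutoff. A cell
exactly at the percentile is kept. Because the threshold is a percentile,
re-filtering an already filtered matrix recomputes it and may remove further
cells; filtering is order-stable but only idempotent at a saturated
threshold.

Feature selection keeps the bins with the highest across-cell variance
(ties broken in genomic order); the criterion is deliberately simple and
monotone. The heterogeneity score always uses the full bin set unless the
caller passes a reduced matrix explicitly.

## Coordinates and formats

Input tables (Ginkgo SegCopy-style wide TSV and a long dialect) are read as
1-based inclusive intervals and stored 0-based half-open; writers convert
back, and gzip is transparent. Missing values are refused rather than
imputed — bin-based callers emit complete matrices, and silent imputation
would bias distances. Sample labels ride along as a `#sample_labels` comment
line in the wide dialect and a `sample` column in the long one, so a written
matrix round-trips exactly, labels included.

## The simulator

The generative model grows a binary cell-division tree from one diploid
founder cell. Defaults, chosen once as a realistic desk-scale
parameterisation:

- **Topology**: at each division one extant cell is chosen uniformly at
  random (`split_shape = 0`), giving a Yule tree; a positive shape switches
  to a beta-splitting construction in which each division hands its
  daughters Beta(shape, shape)-distributed fractions of the parent's
  division propensity.
- **Events per edge**: Poisson with mean `events_per_division = 1`.
- **Event size**: Exponential with mean `theta = 2.5 Mb` (the midpoint of
  the U[500 bp, 5 Mb] range used in the parameter-independence study),
  placed uniformly on the genome and truncated at the chromosome end.
- **Event magnitude**: Geometric with parameter `gain_p = 0.5` (mean 2
  copies); an event is a deletion with probability `loss_fraction = 0.5`.
- **Copy-number floor**: CN is floored at 0, and fully deleted bins are
  immune to later gains — deleted DNA cannot re-amplify.
- **Genome**: 22 autosome-like chromosomes (~3.1 Gbp) at 500 kb bins by
  default; the experiments run on a reduced profile (one 100 Mbp chromosome,
  100 kb bins, 1000 bins) that keeps runtimes at desk scale without changing
  the score's behaviour, which depends on distance *ratios*.

Whole-genome doubling, breakage–fusion–bridge cycles and focal
amplification hotspots are not modelled. "The first k generated cells" are
the extant cells after the first k − 1 divisions (division = birth order);
their progenies partition the leaves and define the segregated subsamples.
The metastasis scenario snapshots one extant cell's CN state when the
primary tree has generated a quarter (early) or three quarters (late) of its
final cell count and grows a second tree from that state; the seeding
fractions follow the stated defaults and are configurable. MRCA distance
between two samples is the number of edges between their founding cells on
the parental tree.

## Experiments and problem sizes

The drivers run on the reduced genome with desk-scale sizes: 20 replicates
of 1000-leaf trees for the regional scenario, 20 early + 20 late
primary/metastasis pairs of 500 cells each, 100 parameter draws of
1000-leaf trees for the independence study, one 10,000-leaf tree with the
first 20 founders (interquartile-filtered to balance sample sizes, ~45
pairs) for the MRCA correlation, and a founder-depth sweep of
(250 leaves, 5 founders) × 6 trees, (1000, 20) × 3 and (4000, 80) × 1 with
~50 cells per sample throughout, so founder depth is the only quantity that
varies. Mann–Whitney U comparisons are two-sided, exact for group sizes
≤ 20 and normal-approximated above; correlations are Pearson. Every report
derives all randomness from one seed, and its summary statistics
(min/max/median/IQR) are recomputable from the stored per-replicate table.

## What the simulations do and do not show

The simulator produces noise-free integer CN states: no amplification
dropout, no replication-phase artefacts, no caller segmentation errors, no
doublets. Passing the simulation suite therefore shows that the score
behaves correctly on clean profiles with known clonal structure; on real
data the preprocessing filters stand in for the missing noise model, and
absolute score levels will differ.

Absolute simulated score levels depend on the generative constants above
(event rate, sizes, magnitudes, topology), which is why the validation
checks assert ordering relations, bands and correlations rather than exact
medians. One visible consequence of the Poisson(1) event rate: occasionally
the few divisions separating the early founders carry no CNA events, so a
"segregated" replicate's subsamples are genuinely indistinguishable and its
score lands at the intermixed null level — the segregated score distribution
has a heavy left tail, and its separation from the null is a statement about
medians and distributions, not about every single tree. The depth studies
show relative, not absolute, agreement: deeper founders give higher scores
at any fixed per-sample cardinality.

## Numerical choices

Distances use `scipy`'s exact cityblock routine; for integer inputs all
distances are integers represented exactly, and the silhouette values agree
with an independent brute-force computation to 1e-12. The heatmap's
hierarchical clustering runs on the same L1 distance matrix as the score
(ward linkage by default, average and complete exposed; ward's variance
interpretation strictly assumes Euclidean distances, so for purists average
linkage is the L1-consistent choice). Partition ranking breaks score ties by
fewer blocks, then canonical name, making scan output deterministic.
Embeddings and stochastic clusterers take explicit seeds; UMAP is imported
lazily and pinned to a single thread for determinism.

## Interface

The package is a library: the importable API plus the narrative scripts in
`examples/` are the intended interface, and the experiment drivers are
plain seeded functions rather than a shell tool, which keeps every
capability scriptable from Python.
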