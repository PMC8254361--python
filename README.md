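# spathet

Spatial intra-tumor heterogeneity from single-cell copy-number data.

Tumors are mosaics of subclones — cell populations distinguished by the
copy-number aberrations (CNAs) they have accumulated. When several samples of
one tumor are available (spatial sections, multi-region biopsies, a primary
and its metastasis), a natural question is whether those samples contain the
*same* mixture of subclones (spatially well-mixed) or genetically *different*
ones (spatially segregated). `spathet` answers this from the per-cell
copy-number matrices produced by single-cell CNA callers (Ginkgo, Cell Ranger
DNA, and similar bin-based callers), for bioinformaticians analysing
low-coverage single-cell whole-genome DNA sequencing.

## The score

Cells are points described by their binned CN profile; the sample each cell
came from plays the role of its cluster. With L1 (Manhattan) distances
`d(p, q) = Σ_bins |CN_p − CN_q|`, define for each cell `p` in sample `S_p`:

    a(p)  = (1 / (|S_p| − 1)) Σ_{q ∈ S_p, q ≠ p} d(p, q)        mean intra-sample distance
    b(p)  = min_{k ≠ p's sample} (1 / |S_k|) Σ_{q ∈ S_k} d(p, q) nearest other sample
    sh(p) = (b(p) − a(p)) / max{a(p), b(p)}

The **Spatial Heterogeneity score** of samples `S_1 … S_n` is the plain mean
of `sh(p)` over all cells of the pooled dataset. It lives in [−1, 1]:
near 1, samples are internally homogeneous and mutually segregated; near 0,
cells could belong to any sample; clearly negative values usually indicate
quality problems. From simulation, scores below 0.2 are best read as
"well-mixed or negligibly separated"; the threshold annotates outputs but
never gates computation. Beyond scoring one grouping, the partition scan
evaluates every way of merging the input samples into ≥ 2 groups and ranks
them, exposing which samples are clonally related.

The package also ships the tumor-evolution simulator used to validate the
score: a Yule/beta-splitting cell-division tree whose edges accrue CNA events
(exponentially sized segments, geometrically distributed copy gains/losses),
plus scenario constructors for spatial segregation, intermixing, metastasis
seeding, and founder-depth studies, and seeded experiment drivers over them.

## Worked example

`examples/simulate_scenarios.py` simulates one 1000-cell tumor and scores the
same cells under a segregated and an intermixed grouping:

```
tree: 1000 leaves, 1999 nodes
SHscore, founder-progeny grouping (segregated): +0.1799
SHscore, shuffled grouping (intermixed):        -0.0195
```

The shuffled grouping is the null: random subsamples of one population are
interchangeable, so the score is ~0 (slightly negative). The founder-progeny
grouping carries real divergence and scores clearly positive.

`examples/partition_scan.py` ranks every grouping of three samples, two of
which are draws from the same clone:

```
     partition  n_blocks    score interpretation
   s1+s2 vs s3         2 0.708312     segregated
s1 vs s2 vs s3         3 0.236363     segregated
   s1 vs s2+s3         2 0.111463     well-mixed
   s1+s3 vs s2         2 0.110455     well-mixed

best partition: s1+s2 vs s3 (SHscore 0.7083)
```

The top partition merges the clonally related samples — exactly how the scan
is used to spot related tumor regions. The other examples cover loading
SegCopy-style caller output and drawing the aggregated heatmap
(`load_and_visualize.py`), cell filtering by ploidy and MAD
(`filter_cells.py`), two-sample scoring (`score_two_samples.py`), and the
clustering wrappers (`cluster_and_evaluate.py`).

## Layout

- `src/spathet/cnvdata.py` — CN matrix container, SegCopy/long TSV readers
  and writers, multi-sample aggregation
- `src/spathet/preprocess.py` — ploidy/MAD annotation and filtering, variable
  feature selection, PCA/UMAP embeddings
- `src/spathet/het.py` — distances, per-cell sh, SHscore, partition
  enumeration and scan, aggregated heatmap
- `src/spathet/clustering.py` — uniform wrappers over eight clustering
  algorithms and seven quality metrics
- `src/spathet/sim.py` — the cell-division simulator and scenario constructors
- `src/spathet/experiments.py` — seeded drivers and reports
- `docs/methods.md` — model details, defaults, and limitations
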