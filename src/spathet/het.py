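"""Spatial Heterogeneity score (SHscore) over multi-sample scCNA data.

The SHscore quantifies how much the copy-number landscapes of several
samples of one tumor have diverged, relative to the internal variability
of each sample.  It is a silhouette-style statistic: cells are data
points described by their copy-number profile and the sample each cell
came from plays the role of its cluster.  For a cell ``p`` in sample
``S_p``::

    a(p) = mean L1 distance from p to the other cells of S_p
    b(p) = min over other samples S_k of the mean L1 distance from p to S_k
    sh(p) = (b(p) - a(p)) / max(a(p), b(p))

and the SHscore of a sample partition is the plain mean of ``sh(p)`` over
every cell of the pooled dataset.  Distances are L1 (Manhattan) over all
bins: for the dimensionality of binned CN profiles, fractional/low-order
norms discriminate neighbours better than the Euclidean norm.

Scores live in ``[-1, 1]``: near 1, samples are internally homogeneous and
mutually segregated; near 0, cells could belong to any sample (well-mixed
subclones or very similar samples); clearly negative values usually flag
quality problems.  As a rule of thumb from simulation, scores below
:data:`MIXING_THRESHOLD` (0.2) indicate spatially well-mixed subclones;
the threshold only annotates outputs, it never gates computation.

Beyond scoring one grouping, :func:`partition_scan` evaluates every way of
merging the input samples into >= 2 groups (all set partitions) and ranks
them, so the most natural spatial arrangement of a tumor's samples can be
read off the top of the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cnvdata import CNVMatrix

#: simulation-derived interpretation threshold: below it, subclones are
#: considered well-mixed (or their spatial differences negligible)
MIXING_THRESHOLD = 0.2

#: partition enumeration cap (Bell-number growth) without explicit override
MAX_SCAN_SAMPLES = 6


class PartitionError(ValueError):
    """Invalid sample partition."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of pairwise cell distances."""

    values: np.ndarray
    metric: str = "l1"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _dist_values(D) -> np.ndarray:
    return D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)


def pairwise_distance(matrix, metric: str = "l1") -> DistanceMatrix:
    """Full cell x cell L1 distance matrix.

    Exact (no approximate neighbours); for integer inputs the distances
    are integers represented exactly in floating point.  ``matrix`` may be
    a :class:`CNVMatrix` or a plain (cells x bins) array.
    """
    if metric != "l1":
        raise ValueError(f"unsupported metric {metric!r}; only 'l1'")
    X = matrix.X if isinstance(matrix, CNVMatrix) else np.asarray(matrix)
    if X.shape[0] < 2:
        raise ValueError("pairwise distances need >= 2 cells")
    D = squareform(pdist(X.astype(float), metric="cityblock"))
    return DistanceMatrix(D, metric="l1")


# ---------------------------------------------------------------------------
# per-cell silhouette machinery
# ---------------------------------------------------------------------------

def mean_intra_distance(p: int, grouping, D) -> float:
    """a(p): mean distance from cell ``p`` to the other cells of its block."""
    D = _dist_values(D)
    grouping = np.asarray(grouping)
    own = grouping == grouping[p]
    size = int(own.sum())
    if size < 2:
        raise PartitionError(f"cell {p} is alone in its block; a(p) undefined")
    return float(D[p, own].sum() / (size - 1))


def min_mean_inter_distance(p: int, grouping, D) -> float:
    """b(p): smallest mean distance from ``p`` to any other block."""
    D = _dist_values(D)
    grouping = np.asarray(grouping)
    others = [g for g in pd.unique(grouping) if g != grouping[p]]
    if not others:
        raise PartitionError("b(p) needs >= 2 blocks")
    return min(float(D[p, grouping == g].mean()) for g in others)


def cell_sh(a: float, b: float) -> float:
    """sh(p) = (b - a) / max(a, b); 0 when a = b = 0 (indifference)."""
    if a < 0 or b < 0:
        raise ValueError("a(p) and b(p) must be non-negative")
    m = max(a, b)
    if m == 0:
        return 0.0
    return (b - a) / m


def _sh_from_block_sums(block_sums: np.ndarray, block_sizes: np.ndarray,
                        codes: np.ndarray) -> np.ndarray:
    """Vectorized sh(p) from per-block distance sums.

    ``block_sums[i, k]`` is the summed distance from cell ``i`` to every
    cell of block ``k``; ``codes[i]`` is the block of cell ``i``.  Cells in
    singleton blocks get sh = 0 (silhouette convention), as do cells with
    a = b = 0 (exact duplicates across blocks).
    """
    n = block_sums.shape[0]
    idx = np.arange(n)
    own_size = block_sizes[codes]
    a = block_sums[idx, codes] / np.maximum(own_size - 1, 1)
    mean_other = block_sums / block_sizes[np.newaxis, :]
    mean_other[idx, codes] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    sh = np.where(denom > 0, (b - a) / np.where(denom == 0, 1.0, denom), 0.0)
    return np.where(own_size == 1, 0.0, sh)


def silhouette_from_distances(D, grouping) -> np.ndarray:
    """Per-cell sh(p) for an arbitrary grouping over a distance matrix."""
    D = _dist_values(D)
    grouping = np.asarray(grouping)
    uniq, codes = np.unique(grouping, return_inverse=True)
    if len(uniq) < 2:
        raise PartitionError("sh(p) needs >= 2 blocks")
    sums = np.empty((D.shape[0], len(uniq)))
    for k in range(len(uniq)):
        sums[:, k] = D[:, codes == k].sum(axis=1)
    sizes = np.bincount(codes, minlength=len(uniq))
    return _sh_from_block_sums(sums, sizes, codes)


def shscore_from_distances(D, grouping) -> float:
    """SHscore (mean per-cell sh) for a grouping over a distance matrix."""
    return float(silhouette_from_distances(D, grouping).mean())


# ---------------------------------------------------------------------------
# partitions of the sample set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Disjoint, covering assignment of sample labels to >= 2 blocks."""

    blocks: tuple[tuple[str, ...], ...]

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[str]]) -> "Partition":
        canon = []
        seen: set[str] = set()
        for block in blocks:
            b = tuple(sorted(str(s) for s in set(block)))
            if not b:
                raise PartitionError("empty block")
            if seen & set(b):
                raise PartitionError(f"blocks are not disjoint: {sorted(seen & set(b))}")
            seen.update(b)
            canon.append(b)
        if len(canon) < 2:
            raise PartitionError("a partition needs >= 2 blocks")
        return cls(tuple(sorted(canon)))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def name(self) -> str:
        return " vs ".join("+".join(b) for b in self.blocks)

    @property
    def samples(self) -> set[str]:
        return {s for b in self.blocks for s in b}

    def block_of(self) -> dict[str, int]:
        return {s: k for k, b in enumerate(self.blocks) for s in b}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def enumerate_partitions(samples: Sequence[str],
                         max_samples: int = MAX_SCAN_SAMPLES,
                         allow_large: bool = False) -> list[Partition]:
    """All set partitions of ``samples`` into >= 2 blocks (Bell(n) - 1).

    For three samples s1, s2, s3 these are the four groupings
    {s1|s2|s3}, {s1 s2|s3}, {s1 s3|s2}, {s2 s3|s1}.  Ordered by block
    count then canonical name.  Enumeration grows like the Bell numbers,
    so more than ``max_samples`` samples requires ``allow_large=True``.
    """
    from sympy.utilities.iterables import multiset_partitions

    labels = sorted({str(s) for s in samples})
    if len(labels) < 2:
        raise PartitionError("partition enumeration needs >= 2 samples")
    if len(labels) > max_samples and not allow_large:
        raise PartitionError(
            f"{len(labels)} samples exceed the enumeration cap "
            f"({max_samples}); pass allow_large=True to override")
    parts = [Partition.from_blocks(p) for p in multiset_partitions(labels)
             if len(p) >= 2]
    parts.sort(key=lambda p: (p.n_blocks, p.name))
    return parts


# ---------------------------------------------------------------------------
# SHscore over a CNVMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SHResult:
    """Per-cell sh(p) values and their mean (the SHscore) for one partition."""

    partition: Partition
    per_cell_sh: np.ndarray
    score: float

    @property
    def interpretation(self) -> str:
        return ("segregated" if self.score >= MIXING_THRESHOLD
                else "well-mixed")


def _grouping_for(matrix: CNVMatrix, partition: Partition) -> np.ndarray:
    block = partition.block_of()
    unknown = [s for s in matrix.samples if s not in block]
    if unknown:
        raise PartitionError(f"matrix samples {unknown} missing from partition")
    codes = np.array([block[s] for s in matrix.sample_labels])
    present = np.unique(codes)
    if len(present) < partition.n_blocks:
        empty = [partition.blocks[k] for k in range(partition.n_blocks)
                 if k not in present]
        raise PartitionError(f"blocks contribute no cells: {empty}")
    return codes


def shscore(matrix: CNVMatrix, partition: Partition | None = None,
            distances: DistanceMatrix | None = None) -> SHResult:
    """SHscore of ``matrix`` under ``partition`` of its sample labels.

    ``partition`` defaults to one block per sample.  Distances are L1 over
    the full bin set as given (no rounding, no feature selection unless the
    caller already reduced the matrix); pass ``distances`` to reuse a
    precomputed matrix.
    """
    if partition is None:
        partition = Partition.from_blocks([[s] for s in matrix.samples])
    codes = _grouping_for(matrix, partition)
    D = distances if distances is not None else pairwise_distance(matrix)
    sh = silhouette_from_distances(D, codes)
    return SHResult(partition=partition, per_cell_sh=sh,
                    score=float(sh.mean()))


@dataclass(frozen=True)
class PartitionScan:
    """Ranked SHscores over every partition of the input samples."""

    table: pd.DataFrame
    best: Partition
    best_result: SHResult


def partition_scan(matrix: CNVMatrix,
                   max_samples: int = MAX_SCAN_SAMPLES,
                   allow_large: bool = False,
                   distances: DistanceMatrix | None = None) -> PartitionScan:
    """Score every sample partition and rank them by SHscore.

    The cell x cell distance matrix is computed once; each partition's
    block sums are assembled from per-sample sums, so the scan costs one
    distance computation plus O(n_cells * n_samples) per partition.
    Ranking is by score descending, ties broken by fewer blocks then by
    canonical partition name.
    """
    samples = sorted(matrix.samples)
    partitions = enumerate_partitions(samples, max_samples=max_samples,
                                      allow_large=allow_large)
    D = distances if distances is not None else pairwise_distance(matrix)
    Dv = _dist_values(D)
    sample_idx = {s: j for j, s in enumerate(samples)}
    sample_codes = np.array([sample_idx[s] for s in matrix.sample_labels])
    n = Dv.shape[0]
    sample_sums = np.empty((n, len(samples)))
    for j in range(len(samples)):
        sample_sums[:, j] = Dv[:, sample_codes == j].sum(axis=1)
    sample_sizes = np.bincount(sample_codes, minlength=len(samples))

    rows = []
    for part in partitions:
        block = part.block_of()
        member = np.zeros((len(samples), part.n_blocks))
        for s, k in block.items():
            member[sample_idx[s], k] = 1.0
        block_sums = sample_sums @ member
        block_sizes = (sample_sizes @ member).astype(int)
        codes = np.array([block[s] for s in matrix.sample_labels])
        sh = _sh_from_block_sums(block_sums, block_sizes, codes)
        score = float(sh.mean())
        rows.append({"partition": part.name, "n_blocks": part.n_blocks,
                     "score": score,
                     "interpretation": ("segregated" if score >= MIXING_THRESHOLD
                                        else "well-mixed"),
                     "_part": part})
    table = pd.DataFrame(rows)
    table = table.sort_values(["score", "n_blocks", "partition"],
                              ascending=[False, True, True],
                              kind="stable").reset_index(drop=True)
    best = table.loc[0, "_part"]
    table = table.drop(columns="_part")
    best_result = shscore(matrix, best, distances=D)
    return PartitionScan(table=table, best=best, best_result=best_result)


# ---------------------------------------------------------------------------
# aggregated heatmap
# ---------------------------------------------------------------------------

def aggregate_heatmap(matrix: CNVMatrix, linkage: str = "ward",
                      metric: str = "l1", out=None,
                      distances: DistanceMatrix | None = None):
    """Hierarchically cluster cells and draw the multi-sample CN heatmap.

    Cells are clustered on the same L1 distance matrix used for scoring
    (``linkage`` in {ward, average, complete}); rows carry a colour bar
    encoding the sample label so sample segregation is visible at the top
    dendrogram splits.  Returns ``(leaf_order, figure)``; the figure is
    additionally written to ``out`` when given.
    """
    import matplotlib
    import seaborn as sns
    from scipy.cluster import hierarchy

    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    D = distances if distances is not None else pairwise_distance(matrix, metric)
    Z = hierarchy.linkage(squareform(_dist_values(D), checks=False),
                          method=linkage)
    order = hierarchy.leaves_list(Z)

    samples = matrix.samples
    palette = sns.color_palette("husl", len(samples))
    colour = dict(zip(samples, palette))
    row_colors = pd.Series([colour[s] for s in matrix.sample_labels],
                           index=matrix.cells, name="sample")
    data = pd.DataFrame(matrix.X, index=matrix.cells)
    grid = sns.clustermap(data, row_linkage=Z, col_cluster=False,
                          row_colors=row_colors, cmap="RdBu_r", center=2,
                          xticklabels=False,
                          yticklabels=matrix.n_cells <= 60)
    grid.ax_heatmap.set_xlabel("genomic bin")
    if out is not None:
        grid.figure.savefig(out, dpi=120)
    return order, grid.figure
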