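"""Cell filtering and feature preparation for scCNA matrices.

Tumor-focused analyses discard (pseudo-)diploid cells, which carry no
copy-number signal, and cells whose profile is unusually noisy as measured
by the median absolute deviation (MAD) of their copy-number vector -- a
proxy for amplification artefacts and ongoing DNA replication.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cnvdata import CNVMatrix, ValidationError

#: diploid / pseudo-diploid ploidy interval removed by default (closed ends)
DEFAULT_PLOIDY_INTERVAL = (1.6, 2.9)
#: MAD percentile above which cells are considered noisy (strict >)
DEFAULT_MAD_PERCENTILE = 95.0


def compute_ploidy(profile, bin_lengths=None) -> float:
    """Length-weighted mean copy number of one cell.

    If the caller supplied an explicit ploidy annotation, that annotation
    takes precedence over this fallback (see :func:`filter_cells`).
    With ``bin_lengths=None`` all bins weigh equally.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValidationError("empty copy-number profile")
    if bin_lengths is None:
        return float(profile.mean())
    w = np.asarray(bin_lengths, dtype=float)
    if w.sum() <= 0:
        raise ValidationError("bin lengths must not all be zero")
    return float(np.average(profile, weights=w))


def compute_mad(profile) -> float:
    """Median absolute deviation ``median(|x - median(x)|)`` (unscaled)."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValidationError("empty copy-number profile")
    return float(np.median(np.abs(profile - np.median(profile))))


def annotate_cells(matrix: CNVMatrix) -> pd.DataFrame:
    """Per-cell ploidy (length-weighted) and MAD, indexed by cell name."""
    lengths = matrix.bin_lengths
    ploidy = [compute_ploidy(matrix.X[i], lengths) for i in range(matrix.n_cells)]
    mad = [compute_mad(matrix.X[i]) for i in range(matrix.n_cells)]
    return pd.DataFrame({"ploidy": ploidy, "mad": mad}, index=matrix.cells)


@dataclass(frozen=True)
class FilterReport:
    """Cell counts removed at each filtering step.

    ``n_kept + n_removed_ploidy + n_removed_mad == n_input``; a cell failing
    both criteria is counted once, under the ploidy filter (applied first).
    """

    n_input: int
    n_removed_ploidy: int
    n_removed_mad: int
    n_kept: int
    ploidy_interval: tuple[float, float]
    mad_percentile: float

    def as_dict(self) -> dict:
        return asdict(self)


def filter_cells(matrix: CNVMatrix,
                 annotations: pd.DataFrame | None = None,
                 ploidy_interval=DEFAULT_PLOIDY_INTERVAL,
                 mad_percentile: float = DEFAULT_MAD_PERCENTILE,
                 percentile_on_all: bool = False,
                 ) -> tuple[CNVMatrix, FilterReport]:
    """Remove diploid-range cells, then high-MAD cells.

    Cells whose ploidy lies in the closed ``ploidy_interval`` are removed
    first.  The MAD threshold is then the ``mad_percentile``-th percentile
    (linear interpolation between order statistics) of the MADs of the
    *surviving* cells -- noisy-cell flagging is relative to the tumor-cell
    population -- unless ``percentile_on_all`` is set, in which case the
    percentile is taken over all input cells.  Cells strictly above the
    threshold are removed; a cell exactly at the percentile is kept.

    ``annotations`` may carry caller-supplied ``ploidy``/``mad`` columns
    indexed by cell name; missing annotations are computed from the matrix.
    Note the MAD percentile is recomputed on re-filtering an already
    filtered matrix, so filtering is not strictly idempotent unless the
    threshold is saturated (e.g. ``mad_percentile=100``).
    """
    lo, hi = float(ploidy_interval[0]), float(ploidy_interval[1])
    if lo > hi:
        raise ValidationError(f"ploidy interval has low > high: [{lo}, {hi}]")
    if annotations is None:
        ann = annotate_cells(matrix)
    else:
        ann = annotations.reindex(matrix.cells)
        computed = annotate_cells(matrix)
        for col in ("ploidy", "mad"):
            if col not in ann.columns:
                ann[col] = computed[col]
            else:
                ann[col] = ann[col].fillna(computed[col])
    ploidy = ann["ploidy"].to_numpy(dtype=float)
    mad = ann["mad"].to_numpy(dtype=float)

    removed_ploidy = (ploidy >= lo) & (ploidy <= hi)
    survivors = ~removed_ploidy
    pool = mad if percentile_on_all else mad[survivors]
    if pool.size:
        threshold = float(np.percentile(pool, mad_percentile))
        removed_mad = survivors & (mad > threshold)
    else:
        removed_mad = np.zeros_like(survivors)
    keep = survivors & ~removed_mad
    report = FilterReport(
        n_input=matrix.n_cells,
        n_removed_ploidy=int(removed_ploidy.sum()),
        n_removed_mad=int(removed_mad.sum()),
        n_kept=int(keep.sum()),
        ploidy_interval=(lo, hi),
        mad_percentile=float(mad_percentile),
    )
    return matrix.subset_cells(keep), report


def select_variable_features(matrix: CNVMatrix, n_top: int) -> CNVMatrix:
    """Keep the ``n_top`` bins with highest across-cell variance.

    Genomic order is preserved; ties are broken in favour of earlier bins.
    """
    if not 1 <= n_top <= matrix.n_bins:
        raise ValidationError(
            f"n_top must be in [1, {matrix.n_bins}], got {n_top}")
    var = matrix.X.var(axis=0)
    ranked = np.argsort(-var, kind="stable")  # stable => genomic order on ties
    selected = np.sort(ranked[:n_top])
    return matrix.subset_bins(selected)


def reduce_dims(data, method: str = "pca", n_components: int = 2,
                seed: int = 0) -> np.ndarray:
    """Embed cells with PCA or UMAP; deterministic given ``seed``.

    ``data`` may be a :class:`CNVMatrix` or a plain (cells x features)
    array.  Row order of the embedding equals cell order.
    """
    X = data.X if isinstance(data, CNVMatrix) else np.asarray(data)
    X = X.astype(float)
    n_cells, n_feat = X.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components >= min(n_cells, n_feat):
        raise ValidationError(
            f"n_components={n_components} too large for {n_cells} cells x "
            f"{n_feat} features")
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=n_components, svd_solver="full",
                   random_state=seed).fit_transform(X)
    if method == "umap":
        import umap  # deferred: heavy import

        reducer = umap.UMAP(n_components=n_components, random_state=seed,
                            n_jobs=1)
        return np.asarray(reducer.fit_transform(X))
    raise ValidationError(f"unknown reduction method {method!r}")
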