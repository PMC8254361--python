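"""Containers and I/O for single-cell copy-number (scCNA) matrices.

A :class:`CNVMatrix` holds one copy-number value per (cell, genomic bin),
together with the bin coordinates and a per-cell *sample label*.  Samples
(e.g. distinct spatial sections of one tumor) are kept inside a single
aggregated matrix as a label column rather than as separate objects, so
every downstream operation receives one matrix plus one grouping.

Coordinate convention: input tables (Ginkgo "SegCopy"-style and the long
dialect) are read as 1-based inclusive intervals and stored internally as
0-based half-open ``[start, end)``; writers convert back on output.
"""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

BIN_COLUMNS = ("chromosome", "start", "end")

#: comment line used by the wide writer to carry per-cell sample labels
_SAMPLE_HEADER = "#sample_labels"


class CNVError(ValueError):
    """Base class for scCNA data errors."""


class FormatError(CNVError):
    """The input file does not match the declared dialect."""


class ValidationError(CNVError):
    """The parsed data violate a container invariant."""


class BinMismatchError(CNVError):
    """Two matrices do not share an identical bin set."""


class GenomicBin(NamedTuple):
    """One genomic bin, 0-based half-open."""

    chromosome: str
    start: int
    end: int


def _chrom_sort_key(name: str):
    """Natural chromosome order: numeric names first (1..22), then others."""
    s = str(name)
    body = s[3:] if s.lower().startswith("chr") else s
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


class CNVMatrix:
    """Cells x genomic-bins copy-number matrix.

    Parameters
    ----------
    values:
        Array-like of shape ``(n_cells, n_bins)``; non-negative, no missing
        entries.  Floats are accepted (some callers emit fractional copy
        numbers) and are never rounded.
    bins:
        DataFrame with columns ``chromosome``, ``start``, ``end`` (0-based
        half-open).  Bins are sorted into genomic order on construction and
        the value columns are reordered accordingly.
    cells:
        Unique cell identifiers, one per value row.
    sample_labels:
        One sample label per cell; a single string broadcasts to all cells.
    """

    def __init__(self, values, bins: pd.DataFrame, cells: Sequence[str],
                 sample_labels=None):
        X = np.asarray(values)
        if X.ndim != 2:
            raise ValidationError("values must be a 2-D (cells x bins) array")
        bins = pd.DataFrame(bins).reset_index(drop=True)
        missing = [c for c in BIN_COLUMNS if c not in bins.columns]
        if missing:
            raise ValidationError(f"bin table lacks columns {missing}")
        bins = bins.loc[:, list(BIN_COLUMNS)].copy()
        bins["chromosome"] = bins["chromosome"].astype(str)
        bins["start"] = bins["start"].astype(np.int64)
        bins["end"] = bins["end"].astype(np.int64)

        cells = [str(c) for c in cells]
        if sample_labels is None:
            sample_labels = ["sample"] * len(cells)
        elif isinstance(sample_labels, str):
            sample_labels = [sample_labels] * len(cells)
        sample_labels = np.asarray([str(s) for s in sample_labels], dtype=object)

        # sort bins into genomic order, carrying the value columns along
        order = sorted(range(len(bins)),
                       key=lambda i: (_chrom_sort_key(bins.at[i, "chromosome"]),
                                      int(bins.at[i, "start"])))
        if order != list(range(len(bins))):
            bins = bins.iloc[order].reset_index(drop=True)
            X = X[:, order]

        self.X = X
        self.bins = bins
        self.cells = cells
        self.sample_labels = sample_labels
        self._validate()

    # -- invariants ------------------------------------------------------

    def _validate(self) -> None:
        n_cells, n_bins = self.X.shape
        if len(self.cells) != n_cells:
            raise ValidationError(
                f"{len(self.cells)} cell names for {n_cells} value rows")
        if len(self.bins) != n_bins:
            raise ValidationError(
                f"{len(self.bins)} bins for {n_bins} value columns")
        if len(self.sample_labels) != n_cells:
            raise ValidationError("one sample label required per cell")
        if len(set(self.cells)) != n_cells:
            dupes = pd.Index(self.cells)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate cell identifiers: {dupes}")
        if n_bins and not np.issubdtype(self.X.dtype, np.number):
            raise ValidationError("copy-number values must be numeric")
        if self.X.size:
            if np.issubdtype(self.X.dtype, np.floating) and np.isnan(self.X).any():
                raise ValidationError("missing copy-number entries are refused")
            if (self.X < 0).any():
                raise ValidationError("copy-number values must be >= 0")
        bad = self.bins["start"] >= self.bins["end"]
        if bad.any():
            row = self.bins[bad].iloc[0]
            raise ValidationError(
                f"bin with start >= end on {row.chromosome}:{row.start}-{row.end}")
        for _, grp in self.bins.groupby("chromosome", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"overlapping bins on chromosome {grp['chromosome'].iloc[0]}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    @property
    def bin_lengths(self) -> np.ndarray:
        """Bin sizes in base pairs."""
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def samples(self) -> list[str]:
        """Distinct sample labels, in order of first appearance."""
        return list(pd.unique(self.sample_labels))

    def iter_bins(self) -> Iterator[GenomicBin]:
        for row in self.bins.itertuples(index=False):
            yield GenomicBin(row.chromosome, int(row.start), int(row.end))

    def copy(self) -> "CNVMatrix":
        return CNVMatrix(self.X.copy(), self.bins.copy(), list(self.cells),
                         self.sample_labels.copy())

    def subset_cells(self, selector) -> "CNVMatrix":
        """Row subset by boolean mask or integer indices (order preserved)."""
        idx = np.asarray(selector)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CNVMatrix(self.X[idx], self.bins,
                         [self.cells[i] for i in idx],
                         self.sample_labels[idx])

    def subset_bins(self, selector) -> "CNVMatrix":
        idx = np.asarray(selector)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CNVMatrix(self.X[:, idx], self.bins.iloc[idx], list(self.cells),
                         self.sample_labels.copy())

    def with_sample_labels(self, labels) -> "CNVMatrix":
        return CNVMatrix(self.X, self.bins, list(self.cells), labels)

    def equals(self, other: "CNVMatrix") -> bool:
        return (self.cells == other.cells
                and self.bins.equals(other.bins)
                and np.array_equal(self.X, other.X)
                and np.array_equal(self.sample_labels, other.sample_labels))

    def to_wide_frame(self) -> pd.DataFrame:
        """Bins x cells table with 1-based inclusive coordinates."""
        out = pd.DataFrame({
            "CHR": self.bins["chromosome"],
            "START": self.bins["start"] + 1,
            "END": self.bins["end"],
        })
        for j, cell in enumerate(self.cells):
            out[cell] = self.X[j]
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CNVMatrix({self.n_cells} cells x {self.n_bins} bins, "
                f"samples={self.samples})")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_wide(text_lines: list[str], positional: bool,
                sample_label) -> CNVMatrix:
    labels = None
    if text_lines and text_lines[0].startswith(_SAMPLE_HEADER):
        labels = text_lines[0].rstrip("\n").split("\t")[1:]
        text_lines = text_lines[1:]
    if not text_lines:
        raise FormatError("empty file: header row required")
    header = text_lines[0].rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"duplicate cell names in header: {dupes}")
    from io import StringIO
    try:
        df = pd.read_csv(StringIO("".join(text_lines)), sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas-specific messages
        raise FormatError(f"cannot parse table: {exc}") from exc
    cols = list(df.columns)
    if positional:
        if len(cols) < 3:
            raise FormatError("wide table needs >= 3 leading coordinate columns")
        chrom_c, start_c, end_c = cols[:3]
    else:
        lut = {c.upper(): c for c in cols}
        try:
            chrom_c, start_c, end_c = lut["CHR"], lut["START"], lut["END"]
        except KeyError as exc:
            raise FormatError(
                f"SegCopy table must have CHR/START/END columns, got {cols}"
            ) from exc
    cell_cols = [c for c in cols if c not in (chrom_c, start_c, end_c)]
    try:
        start = pd.to_numeric(df[start_c], errors="raise").astype(np.int64)
        end = pd.to_numeric(df[end_c], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"coordinate columns are not integers: {exc}") from exc
    bins = pd.DataFrame({"chromosome": df[chrom_c].astype(str),
                         "start": start - 1,  # 1-based incl -> 0-based half-open
                         "end": end})
    try:
        values = df[cell_cols].apply(pd.to_numeric, errors="raise").to_numpy().T
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric copy-number value: {exc}") from exc
    if values.size == 0:
        values = values.reshape(len(cell_cols), len(bins))
    if labels is not None:
        if len(labels) != len(cell_cols):
            raise FormatError(f"{_SAMPLE_HEADER} line has {len(labels)} labels "
                              f"for {len(cell_cols)} cells")
        sample = labels
    else:
        sample = sample_label
    return CNVMatrix(values, bins, cell_cols, sample)


def _parse_long(text_lines: list[str], sample_label) -> CNVMatrix:
    from io import StringIO
    try:
        df = pd.read_csv(StringIO("".join(text_lines)), sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse table: {exc}") from exc
    required = ["cell", "chromosome", "start", "end", "copy_number"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"long table lacks columns {missing}")
    try:
        df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
        df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"coordinate columns are not integers: {exc}") from exc
    try:
        df["copy_number"] = pd.to_numeric(df["copy_number"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric copy-number value: {exc}") from exc
    wide = df.pivot_table(index=["chromosome", "start", "end"], columns="cell",
                          values="copy_number", aggfunc="first", sort=False)
    if wide.isna().any().any():
        raise ValidationError("cells do not share an identical bin set")
    bins = wide.index.to_frame(index=False)
    bins["start"] = bins["start"] - 1  # 1-based inclusive -> 0-based half-open
    cells = [str(c) for c in wide.columns]
    if "sample" in df.columns:
        lut = df.drop_duplicates("cell").set_index("cell")["sample"]
        sample = [str(lut[c]) for c in wide.columns]
    else:
        sample = sample_label
    return CNVMatrix(wide.to_numpy().T, bins, cells, sample)


def load_cnv_table(path, format: str = "segcopy",
                   sample_label: str | None = None) -> CNVMatrix:
    """Load a per-cell copy-number table.

    ``format`` is one of ``segcopy`` (Ginkgo-style TSV with CHR/START/END
    columns then one column per cell), ``generic_wide`` (same layout, the
    first three columns taken positionally as coordinates) or
    ``generic_long`` (TSV with cell/chromosome/start/end/copy_number and an
    optional per-cell ``sample`` column).  Gzip input is transparent.
    """
    if format not in ("segcopy", "generic_wide", "generic_long"):
        raise FormatError(f"unknown format {format!r}")
    if sample_label is None:
        sample_label = "sample"
    with _open_text(path, "r") as fh:
        lines = fh.readlines()
    if format == "generic_long":
        return _parse_long(lines, sample_label)
    return _parse_wide(lines, positional=(format == "generic_wide"),
                       sample_label=sample_label)


def write_matrix(matrix: CNVMatrix, path, format: str = "segcopy") -> None:
    """Write ``matrix`` as TSV; ``load_cnv_table`` round-trips it exactly.

    The wide dialect stores the per-cell sample labels in a leading
    ``#sample_labels`` comment line; the long dialect carries them in a
    ``sample`` column.  A ``.gz`` suffix gzips the output.
    """
    if format in ("segcopy", "generic_wide"):
        wide = matrix.to_wide_frame()
        with _open_text(path, "w") as fh:
            fh.write(_SAMPLE_HEADER + "".join(
                "\t" + s for s in matrix.sample_labels) + "\n")
            wide.to_csv(fh, sep="\t", index=False)
    elif format == "generic_long":
        recs = []
        for i, cell in enumerate(matrix.cells):
            recs.append(pd.DataFrame({
                "cell": cell,
                "chromosome": matrix.bins["chromosome"],
                "start": matrix.bins["start"] + 1,
                "end": matrix.bins["end"],
                "copy_number": matrix.X[i],
                "sample": matrix.sample_labels[i],
            }))
        if recs:
            long = pd.concat(recs, ignore_index=True)
        else:
            long = pd.DataFrame(columns=["cell", "chromosome", "start", "end",
                                         "copy_number", "sample"])
        with _open_text(path, "w") as fh:
            long.to_csv(fh, sep="\t", index=False)
    else:
        raise FormatError(f"unknown format {format!r}")


def aggregate(matrices: Iterable[CNVMatrix],
              labels: Sequence[str]) -> CNVMatrix:
    """Row-concatenate per-sample matrices into one multi-sample matrix.

    All inputs must share an identical bin set; each cell of the result
    carries the label of its source matrix and cell order follows the
    concatenation order.
    """
    matrices = list(matrices)
    labels = [str(l) for l in labels]
    if not matrices:
        raise ValidationError("aggregate() needs at least one matrix")
    if len(labels) != len(matrices):
        raise ValidationError("one label required per matrix")
    if len(set(labels)) != len(labels):
        raise ValidationError(f"sample labels must be unique, got {labels}")
    ref = matrices[0].bins
    for m, lab in zip(matrices[1:], labels[1:]):
        if not ref.equals(m.bins):
            if len(ref) != len(m.bins):
                raise BinMismatchError(
                    f"sample {lab!r} has {len(m.bins)} bins, expected {len(ref)}")
            diff = ~(ref == m.bins).all(axis=1)
            row = ref[diff].iloc[0]
            raise BinMismatchError(
                f"sample {lab!r} differs from the reference bin set starting "
                f"at {row.chromosome}:{row.start}-{row.end}")
    values = np.vstack([m.X for m in matrices])
    cells: list[str] = []
    sample: list[str] = []
    for m, lab in zip(matrices, labels):
        cells.extend(m.cells)
        sample.extend([lab] * m.n_cells)
    return CNVMatrix(values, ref, cells, sample)
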