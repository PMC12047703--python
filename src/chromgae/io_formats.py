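"""Readers and writers for the on-disk formats the pipeline touches.

All BED-family coordinates are 0-based half-open; contact-matrix bin
indices are 0-based. Round-trip write→read is the identity at full float
precision for every format here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "ContactMatrix",
    "PairList",
    "ParseError",
    "ValidationError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_contacts",
    "write_contacts",
    "read_pairs",
    "write_pairs",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a format invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak or motif call.

    ``summit_offset`` is relative to ``interval.start``; ``motif_score``
    is used when the record is a motif call (BED6 score column).
    """

    interval: GenomicInterval
    signal: float = 0.0
    summit_offset: Optional[int] = None
    strand: str = "."
    motif_score: Optional[float] = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError(f"signal must be >= 0, got {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValidationError(
                f"summit_offset {self.summit_offset} outside interval of "
                f"length {self.interval.length}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def anchor(self) -> int:
        """Best point estimate of the binding site: summit, else midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass
class ContactMatrix:
    """Binned symmetric contact matrix plus its bin table.

    ``bins`` are sorted, non-overlapping, uniform-width intervals of one
    chromosome; ``values`` is symmetric and nonnegative.
    """

    bins: list[GenomicInterval]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bins)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"values shape {self.values.shape} does not match {n} bins"
            )
        if np.any(self.values < 0):
            raise ValidationError("contact values must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("contact matrix must be symmetric")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValidationError(f"bins overlap: {a} and {b}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_size(self) -> int:
        return self.bins[0].length


@dataclass
class PairList:
    """Known interaction pairs (e.g. eQTL–eGENE, enhancer–gene)."""

    records: list[tuple[GenomicInterval, GenomicInterval, str]] = field(
        default_factory=list
    )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file into Peak records."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: narrowPeak needs >= 10 fields, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                name = parts[3]
                strand = parts[5]
                signal = float(parts[6])
                summit = int(parts[9])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start < 0:
                raise ValidationError(f"{path}: line {lineno}: negative coordinate")
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    signal=signal,
                    summit_offset=None if summit < 0 else summit,
                    strand=strand if strand in ("+", "-") else ".",
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t0\t{p.strand}\t{float(p.signal)!r}\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph

CoverageMap = dict[str, list[tuple[GenomicInterval, float]]]


def read_bedgraph(path) -> CoverageMap:
    """Read a 4-column bedGraph into {chrom: sorted [(interval, value)]}.

    Overlapping intervals within a chromosome are a hard error; adjacent
    records with equal value are retained as-is (no merging).
    """
    out: CoverageMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: bedGraph needs 4 fields, got {len(parts)}"
                )
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                val = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            out.setdefault(iv.chrom, []).append((iv, val))
    for chrom, records in out.items():
        records.sort(key=lambda r: (r[0].start, r[0].end))
        for (a, _), (b, _) in zip(records, records[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"{path}: overlapping bedGraph intervals on {chrom}: {a} and {b}"
                )
    return out


def write_bedgraph(path, coverage: CoverageMap) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            for iv, val in coverage[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{float(val)!r}\n")


# ---------------------------------------------------------------------------
# BED3/BED6 (TAD intervals, motif calls)


def read_bed(path) -> list[Peak]:
    """Read BED3/BED6 records; score column maps to ``motif_score``."""
    out: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >= 3 fields")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 else None
                strand = parts[5] if len(parts) > 5 else "."
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            out.append(
                Peak(
                    interval=iv,
                    motif_score=score,
                    strand=strand if strand in ("+", "-") else ".",
                    name=name,
                )
            )
    return out


def write_bed(path, records: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in records:
            score = 0.0 if p.motif_score is None else float(p.motif_score)
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t{score!r}\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# contact COO triplets + bin table


def read_contacts(path_triplets, path_bins) -> ContactMatrix:
    """Read COO triplets `i j count` and a bin table into a ContactMatrix.

    The matrix is symmetrized by mirroring; duplicate (i, j) entries are
    summed (COO convention); absent pairs are zero.
    """
    bins_df = pd.read_csv(
        path_bins,
        sep="\t",
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    bins = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in bins_df.itertuples()
    ]
    n = len(bins)
    mat = np.zeros((n, n))
    trip = pd.read_csv(
        path_triplets,
        sep="\t",
        names=["i", "j", "count"],
        comment="#",
        float_precision="round_trip",
    )
    if len(trip):
        ii = trip["i"].to_numpy(dtype=np.int64)
        jj = trip["j"].to_numpy(dtype=np.int64)
        cc = trip["count"].to_numpy(dtype=float)
        if ii.min() < 0 or jj.min() < 0 or ii.max() >= n or jj.max() >= n:
            raise ValidationError(
                f"{path_triplets}: bin index out of range [0, {n})"
            )
        np.add.at(mat, (ii, jj), cc)
    upper = np.triu(mat)
    lower = np.tril(mat, -1)
    full = upper + upper.T - np.diag(np.diag(upper)) + lower + lower.T
    return ContactMatrix(bins=bins, values=full)


def write_contacts(path_triplets, path_bins, matrix: ContactMatrix) -> None:
    """Write the upper triangle (incl. diagonal) of nonzero contacts."""
    with open(path_bins, "w") as fh:
        for b in matrix.bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\n")
    ii, jj = np.nonzero(np.triu(matrix.values))
    with open(path_triplets, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{float(matrix.values[i, j])!r}\n")


# ---------------------------------------------------------------------------
# pair lists (7-column TSV)


def read_pairs(path) -> PairList:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(
                    f"{path}: line {lineno}: pair list needs 7 fields"
                )
            a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            records.append((a, b, parts[6]))
    return PairList(records=records)


def write_pairs(path, pairs: PairList) -> None:
    with open(path, "w") as fh:
        for a, b, tag in pairs.records:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{tag}\n"
            )
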