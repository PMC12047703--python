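"""CTCF-based chromosome segmentation and node featurization.

A chromosome is partitioned at CTCF peak anchors (summit if present, else
interval midpoint): k+1 anchors yield k adjacent, non-overlapping segments.
Each segment carries a 14-dimensional feature vector combining positional
information, flanking CTCF peak/motif evidence, and mean coverage of
chromatin tracks; continuous features are log1p-transformed then min–max
scaled to [0, 1] per chromosome so the sigmoid-activated encoder sees
bounded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import CoverageMap, GenomicInterval, Peak

__all__ = [
    "Segment",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "SegmentationError",
    "segment_by_ctcf",
    "featurize",
    "feature_matrix",
    "write_segments",
]

N_FEATURES = 14

#: Names with special (non-track) semantics in a schema.
_POSITIONAL = ("start_scaled", "end_scaled")
_STRUCTURAL = (
    "ctcf5_signal",
    "ctcf3_signal",
    "ctcf5_motif",
    "ctcf3_motif",
    "ctcf5_strand",
    "ctcf3_strand",
    "log_length",
)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 14-feature schema shared by all segments of a dataset.

    Names not in the positional/structural vocabulary are coverage-track
    names resolved against the ``tracks`` mapping at featurization time.
    ``positional_mode`` controls the two positional columns: genomic
    ``coordinates``, sinusoidal ``rank_encoding`` of the segment rank, or
    ``none`` (columns fixed at zero, for the positional ablation).
    """

    names: tuple[str, ...] = ()
    positional_mode: str = "coordinates"

    def __post_init__(self) -> None:
        if len(self.names) != N_FEATURES:
            raise SegmentationError(
                f"schema must have exactly {N_FEATURES} names, got {len(self.names)}"
            )
        if self.positional_mode not in ("coordinates", "rank_encoding", "none"):
            raise SegmentationError(
                f"unknown positional_mode {self.positional_mode!r}"
            )

    @property
    def track_names(self) -> tuple[str, ...]:
        return tuple(
            n for n in self.names if n not in _POSITIONAL and n not in _STRUCTURAL
        )


DEFAULT_SCHEMA = FeatureSchema(
    names=(
        "start_scaled",
        "end_scaled",
        "ctcf5_signal",
        "ctcf3_signal",
        "ctcf5_motif",
        "ctcf3_motif",
        "ctcf5_strand",
        "ctcf3_strand",
        "dnase",
        "rad21",
        "polr2a",
        "h3k4me3",
        "h3k27ac",
        "log_length",
    )
)


@dataclass
class Segment:
    """A CTCF-delimited chromatin interval with its feature vector."""

    interval: GenomicInterval
    index: int
    peak5: Optional[Peak] = None
    peak3: Optional[Peak] = None
    features: Optional[np.ndarray] = None
    feature_names: Optional[tuple[str, ...]] = None


def segment_by_ctcf(
    peaks: list[Peak], chrom_span: Optional[GenomicInterval] = None
) -> list[Segment]:
    """Partition a chromosome at CTCF peak anchors.

    k peaks yield k−1 segments; segment i spans [anchor_i, anchor_{i+1})
    and records its flanking 5′ and 3′ peaks. Peaks must all be on one
    chromosome and are sorted by anchor internally.
    """
    if len(peaks) < 2:
        raise SegmentationError("chromosome cannot be segmented: fewer than 2 peaks")
    chroms = {p.interval.chrom for p in peaks}
    if len(chroms) != 1:
        raise SegmentationError(f"peaks span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    if chrom_span is not None and chrom_span.chrom != chrom:
        raise SegmentationError("chrom_span chromosome does not match peaks")
    ordered = sorted(peaks, key=lambda p: p.anchor)
    segments = []
    for k, (p5, p3) in enumerate(zip(ordered, ordered[1:])):
        a, b = p5.anchor, p3.anchor
        if a == b:
            raise SegmentationError(
                f"coincident peak anchors at {chrom}:{a}; cannot form a segment"
            )
        segments.append(
            Segment(
                interval=GenomicInterval(chrom, a, b),
                index=k,
                peak5=p5,
                peak3=p3,
            )
        )
    return segments


def _mean_coverage(
    track: list[tuple[GenomicInterval, float]], starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Length-weighted mean of a sorted non-overlapping track per segment."""
    t_start = np.array([iv.start for iv, _ in track])
    t_end = np.array([iv.end for iv, _ in track])
    t_val = np.array([v for _, v in track])
    out = np.zeros(len(starts))
    for k, (s, e) in enumerate(zip(starts, ends)):
        lo = np.searchsorted(t_end, s, side="right")
        hi = np.searchsorted(t_start, e, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(t_end[lo:hi], e) - np.maximum(t_start[lo:hi], s)
        out[k] = float(np.dot(ov, t_val[lo:hi])) / (e - s)
    return out


def _best_motif(motifs: list[Peak], anchor: int, window: int = 500) -> Optional[Peak]:
    """Highest-scoring motif call whose interval covers anchor ± window."""
    best = None
    for m in motifs:
        if m.interval.start < anchor + window and anchor - window < m.interval.end:
            if best is None or (m.motif_score or 0.0) > (best.motif_score or 0.0):
                best = m
    return best


def _minmax_log1p(v: np.ndarray) -> np.ndarray:
    v = np.log1p(np.maximum(v, 0.0))
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-300:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def featurize(
    segments: list[Segment],
    tracks: dict[str, list[tuple[GenomicInterval, float]]] | CoverageMap,
    motifs: Optional[list[Peak]] = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> list[Segment]:
    """Fill the 14-feature vector of every segment, in place.

    Track columns are length-weighted mean coverage; CTCF columns come
    from the flanking peaks recorded at segmentation; motif columns from
    the strongest motif call near each flanking anchor (score 0 / strand
    0 when absent). Continuous columns are log1p + min–max scaled per
    chromosome; strand columns are {+1, −1, 0} untouched.
    """
    if not segments:
        return segments
    motifs = motifs or []
    chrom = segments[0].interval.chrom
    if isinstance(next(iter(tracks.values()), None), dict):
        # tracks given as {name: CoverageMap}
        tracks = {name: cov.get(chrom, []) for name, cov in tracks.items()}
    for name in schema.track_names:
        if name not in tracks:
            raise SegmentationError(f"schema names track {name!r} but it is missing")

    n = len(segments)
    starts = np.array([s.interval.start for s in segments], dtype=float)
    ends = np.array([s.interval.end for s in segments], dtype=float)
    cols: dict[str, np.ndarray] = {}

    if schema.positional_mode == "coordinates":
        cols["start_scaled"] = _minmax_log1p(starts)
        cols["end_scaled"] = _minmax_log1p(ends)
    elif schema.positional_mode == "rank_encoding":
        rank = np.arange(n, dtype=float)
        cols["start_scaled"] = 0.5 * (1.0 + np.sin(rank / 100.0))
        cols["end_scaled"] = 0.5 * (1.0 + np.cos(rank / 100.0))
    else:  # none — positional ablation
        cols["start_scaled"] = np.zeros(n)
        cols["end_scaled"] = np.zeros(n)

    cols["ctcf5_signal"] = _minmax_log1p(
        np.array([s.peak5.signal if s.peak5 else 0.0 for s in segments])
    )
    cols["ctcf3_signal"] = _minmax_log1p(
        np.array([s.peak3.signal if s.peak3 else 0.0 for s in segments])
    )

    strand_code = {"+": 1.0, "-": -1.0, ".": 0.0}
    m5 = [
        _best_motif(motifs, s.peak5.anchor) if s.peak5 else None for s in segments
    ]
    m3 = [
        _best_motif(motifs, s.peak3.anchor) if s.peak3 else None for s in segments
    ]
    cols["ctcf5_motif"] = _minmax_log1p(
        np.array([(m.motif_score or 0.0) if m else 0.0 for m in m5])
    )
    cols["ctcf3_motif"] = _minmax_log1p(
        np.array([(m.motif_score or 0.0) if m else 0.0 for m in m3])
    )
    cols["ctcf5_strand"] = np.array(
        [strand_code[m.strand] if m else 0.0 for m in m5]
    )
    cols["ctcf3_strand"] = np.array(
        [strand_code[m.strand] if m else 0.0 for m in m3]
    )
    cols["log_length"] = _minmax_log1p(ends - starts)

    for name in schema.track_names:
        cols[name] = _minmax_log1p(
            _mean_coverage(tracks[name], starts, ends)
        )

    X = np.column_stack([cols[name] for name in schema.names])
    assert np.all(np.isfinite(X))
    for k, seg in enumerate(segments):
        seg.features = X[k]
        seg.feature_names = schema.names
    return segments


def feature_matrix(segments: list[Segment]) -> np.ndarray:
    """Stack per-segment features into the (n_segments × 14) matrix."""
    if any(s.features is None for s in segments):
        raise SegmentationError("segments are not featurized")
    return np.vstack([s.features for s in segments])


def write_segments(path, segments: list[Segment]) -> None:
    """Write segments as BED6+ with the 14 feature columns and a header."""
    names = segments[0].feature_names if segments else DEFAULT_SCHEMA.names
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t" + "\t".join(names) + "\n")
        for s in segments:
            feats = "\t".join(repr(float(v)) for v in s.features)
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"seg_{s.index}\t0\t.\t{feats}\n"
            )
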