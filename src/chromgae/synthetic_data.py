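"""Synthetic chromatin datasets with planted TAD structure.

The generator emulates the statistical shape of the real inputs without
any download: CTCF peaks sit at every segment boundary with a 3× signal
boost at TAD boundaries; TAD sizes are geometric with mean 9 segments
(the cis-interaction range the model's signed weights are built
around); true segment-pair scores follow an exponential distance decay
multiplied by a within-TAD enrichment factor and multiplicative
log-normal noise; activity tracks (DNase, POLR2A, H3K4me3, H3K27ac) are
elevated inside a random subset of "active" TADs, RAD21 tracks the CTCF
signal, and one deliberately uninformative noise track gives the
explainer a negative control. Everything is emitted in the package's
on-disk formats plus truth files, and is byte-reproducible for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hic_processing import SegmentScoreMap, write_score_map
from .io_formats import (
    ContactMatrix,
    GenomicInterval,
    PairList,
    Peak,
    write_bed,
    write_bedgraph,
    write_contacts,
    write_narrowpeak,
    write_pairs,
)
from .segmentation import FeatureSchema, Segment, feature_matrix, featurize, segment_by_ctcf

__all__ = [
    "SynthConfig",
    "SynthChromosome",
    "SynthTruth",
    "SYNTH_SCHEMA",
    "generate",
    "build_training_dataset",
    "truth_report",
]

#: Feature schema for synthetic runs: the pure-noise track replaces rad21
#: (which the generator makes redundant with the flanking-CTCF features),
#: keeping 14 features and giving the explainer its negative control.
SYNTH_SCHEMA = FeatureSchema(
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
        "noise",
        "polr2a",
        "h3k4me3",
        "h3k27ac",
        "log_length",
    )
)

#: Contact amplitude at zero distance (arbitrary balanced-count units).
AMPLITUDE = 30.0
#: Median segment length in bp (log-normal, sigma below).
SEGMENT_MEDIAN_BP = 50_000
SEGMENT_SIGMA = 0.4
TRACK_STEP_BP = 5_000
CTCF_BOUNDARY_BOOST = 3.0
ACTIVITY_BOOST = 3.0


@dataclass(frozen=True)
class SynthConfig:
    n_segments: int = 300
    n_chroms: int = 4
    mean_tad_size: int = 9
    distance_decay_length: float = 1_000_000.0
    tad_boost: float = 1.5
    noise_sd: float = 0.3
    active_fraction: float = 0.5
    bin_size: int = 20_000
    max_span: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_segments, self.n_chroms, self.mean_tad_size,
               self.bin_size, self.max_span) <= 0:
            raise ValueError("all size parameters must be positive")
        if self.distance_decay_length <= 0 or self.tad_boost < 0:
            raise ValueError("decay length must be > 0 and tad_boost >= 0")
        if not (0 <= self.active_fraction <= 1):
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SynthChromosome:
    """In-memory truth and inputs for one synthetic chromosome."""

    chrom: str
    anchors: np.ndarray  # n_segments + 1 boundary anchors (bp)
    peaks: list[Peak]
    motifs: list[Peak]
    tracks: dict[str, list[tuple[GenomicInterval, float]]]
    tad_bounds: np.ndarray  # TAD k covers segments [tad_bounds[k], tad_bounds[k+1])
    active: np.ndarray  # bool per TAD
    true_scores: SegmentScoreMap
    raw_scores: dict[tuple[int, int], float]  # pre-log1p, for the bin map

    @property
    def n_segments(self) -> int:
        return len(self.anchors) - 1

    @property
    def tads(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(
                self.chrom,
                int(self.anchors[self.tad_bounds[k]]),
                int(self.anchors[self.tad_bounds[k + 1]]),
            )
            for k in range(len(self.tad_bounds) - 1)
        ]

    def segment_tad(self, i: int) -> int:
        """TAD index containing segment i."""
        return int(np.searchsorted(self.tad_bounds, i, side="right")) - 1

    def contact_matrix(self) -> ContactMatrix:
        """Bin-level map consistent with the true scores.

        Each bin belongs to the segment containing its midpoint; the
        block of bin pairs for segment pair (i, j) is filled uniformly
        with the raw (pre-log1p) score, so mean-aggregation followed by
        log1p recovers the truth up to boundary-bin mixing.
        """
        bs = self._bin_size
        end = int(self.anchors[-1])
        n_bins = int(np.ceil(end / bs))
        bins = [
            GenomicInterval(self.chrom, a * bs, (a + 1) * bs) for a in range(n_bins)
        ]
        mid = np.array([(b.start + b.end) // 2 for b in bins])
        owner = np.searchsorted(self.anchors, mid, side="right") - 1
        owner[(mid < self.anchors[0]) | (mid >= self.anchors[-1])] = -1
        M = np.zeros((n_bins, n_bins))
        by_seg: dict[int, np.ndarray] = {}
        for s in range(self.n_segments):
            by_seg[s] = np.where(owner == s)[0]
        for (i, j), r in self.raw_scores.items():
            bi, bj = by_seg.get(i), by_seg.get(j)
            if bi is None or bj is None or not len(bi) or not len(bj):
                continue
            M[np.ix_(bi, bj)] = r
            M[np.ix_(bj, bi)] = r
        return ContactMatrix(bins=bins, values=M)

    _bin_size: int = 20_000


@dataclass
class SynthTruth:
    """Ground truth across chromosomes plus the planted known pairs."""

    config: SynthConfig
    chromosomes: dict[str, SynthChromosome]
    planted_known_pairs: PairList

    @property
    def tads(self) -> list[GenomicInterval]:
        return [t for c in self.chromosomes.values() for t in c.tads]

    @property
    def active_tads(self) -> set[tuple[str, int]]:
        return {
            (name, k)
            for name, c in self.chromosomes.items()
            for k in np.flatnonzero(c.active)
        }


def _make_chromosome(
    chrom: str, cfg: SynthConfig, rng: np.random.Generator
) -> SynthChromosome:
    n = cfg.n_segments
    lengths = rng.lognormal(np.log(SEGMENT_MEDIAN_BP), SEGMENT_SIGMA, n)
    lengths = np.maximum(lengths.astype(int), 2_000)
    anchors = 10_000 + np.concatenate([[0], np.cumsum(lengths)])

    # geometric TAD sizes, mean = mean_tad_size segments
    sizes = []
    total = 0
    while total < n:
        s = int(rng.geometric(1.0 / cfg.mean_tad_size))
        sizes.append(min(s, n - total))
        total += sizes[-1]
    tad_bounds = np.concatenate([[0], np.cumsum(sizes)])
    n_tads = len(sizes)
    active = rng.random(n_tads) < cfg.active_fraction
    is_tad_boundary = np.zeros(n + 1, dtype=bool)
    is_tad_boundary[tad_bounds] = True

    peaks, motifs = [], []
    for a_idx, a in enumerate(anchors):
        half = int(rng.integers(150, 350))
        signal = rng.gamma(2.0, 2.0)
        if is_tad_boundary[a_idx]:
            signal *= CTCF_BOUNDARY_BOOST
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, int(a - half), int(a + half)),
                signal=float(signal),
                summit_offset=half,
                name=f"{chrom}_p{a_idx}",
            )
        )
        # forward motifs open domains; interior anchors are random
        if is_tad_boundary[a_idx] and a_idx < n:
            strand = "+"
        elif a_idx == n:
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        motifs.append(
            Peak(
                interval=GenomicInterval(chrom, int(a - 10), int(a + 9)),
                motif_score=float(signal * rng.uniform(1.0, 2.0)),
                strand=strand,
                name=f"{chrom}_m{a_idx}",
            )
        )

    mids = (anchors[:-1] + anchors[1:]) / 2.0
    seg_tad = np.searchsorted(tad_bounds, np.arange(n), side="right") - 1
    raw: dict[tuple[int, int], float] = {}
    log_scores: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, min(i + cfg.max_span, n - 1) + 1):
            g = abs(mids[j] - mids[i])
            same = seg_tad[i] == seg_tad[j]
            noise = rng.lognormal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 1.0
            r = (
                AMPLITUDE
                * np.exp(-g / cfg.distance_decay_length)
                * (1.0 + cfg.tad_boost * same)
                * noise
            )
            raw[(i, j)] = float(r)
            log_scores[(i, j)] = float(np.log1p(r))

    # tracks on a fixed 5-kb grid; activity elevated in active TADs
    end = int(anchors[-1])
    grid = np.arange(0, end + TRACK_STEP_BP, TRACK_STEP_BP)
    centers = (grid[:-1] + grid[1:]) / 2.0
    in_seg = np.searchsorted(anchors, centers, side="right") - 1
    in_seg = np.clip(in_seg, 0, n - 1)
    tad_of_win = seg_tad[in_seg]
    is_active_win = active[tad_of_win] & (centers >= anchors[0]) & (centers < anchors[-1])
    tracks: dict[str, list[tuple[GenomicInterval, float]]] = {}
    for name in ("dnase", "polr2a", "h3k4me3", "h3k27ac"):
        base = rng.gamma(2.0, 1.0, len(centers))
        vals = base * np.where(is_active_win, 1.0 + ACTIVITY_BOOST, 1.0)
        tracks[name] = _grid_track(chrom, grid, vals)
    peak_signal_at = np.zeros(len(centers))
    win_of_anchor = np.clip(anchors // TRACK_STEP_BP, 0, len(centers) - 1)
    for a_idx, w in enumerate(win_of_anchor):
        peak_signal_at[int(w)] += peaks[a_idx].signal
    tracks["rad21"] = _grid_track(
        chrom, grid, 0.2 * rng.gamma(2.0, 1.0, len(centers)) + 0.8 * peak_signal_at
    )
    tracks["noise"] = _grid_track(chrom, grid, rng.gamma(2.0, 1.0, len(centers)))

    return SynthChromosome(
        chrom=chrom,
        anchors=anchors,
        peaks=peaks,
        motifs=motifs,
        tracks=tracks,
        tad_bounds=tad_bounds,
        active=active,
        true_scores=SegmentScoreMap(
            pairs=log_scores, normalization="none", log_transformed=True
        ),
        raw_scores=raw,
        _bin_size=cfg.bin_size,
    )


def _grid_track(chrom, grid, vals):
    return [
        (GenomicInterval(chrom, int(a), int(b)), float(round(v, 6)))
        for a, b, v in zip(grid[:-1], grid[1:], vals)
    ]


def _planted_pairs(chromosomes: dict[str, SynthChromosome]) -> PairList:
    """Top-decile within-active-TAD pairs, as segment-interval pairs."""
    records = []
    for name, c in chromosomes.items():
        eligible = []
        for (i, j), s in c.true_scores.pairs.items():
            ti, tj = c.segment_tad(i), c.segment_tad(j)
            if ti == tj and c.active[ti]:
                eligible.append(((i, j), s))
        if not eligible:
            continue
        cutoff = np.quantile([s for _, s in eligible], 0.9)
        for (i, j), s in eligible:
            if s >= cutoff:
                a = GenomicInterval(name, int(c.anchors[i]), int(c.anchors[i + 1]))
                b = GenomicInterval(name, int(c.anchors[j]), int(c.anchors[j + 1]))
                records.append((a, b, "planted"))
    return PairList(records=records)


def generate(
    cfg: SynthConfig, out_dir: Optional[str] = None
) -> tuple[Optional[dict[str, str]], SynthTruth]:
    """Build the synthetic dataset; write files when out_dir is given.

    Returns (paths, truth); paths is None for in-memory use. Output is
    deterministic (byte-identical files) for a fixed config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    chromosomes = {}
    for c in range(cfg.n_chroms):
        name = f"chr{c + 1}"
        chromosomes[name] = _make_chromosome(name, cfg, rng)
    truth = SynthTruth(
        config=cfg,
        chromosomes=chromosomes,
        planted_known_pairs=_planted_pairs(chromosomes),
    )
    if out_dir is None:
        return None, truth

    import os

    os.makedirs(out_dir, exist_ok=True)
    p = lambda fn: os.path.join(out_dir, fn)
    paths: dict[str, str] = {}

    all_peaks = [pk for c in chromosomes.values() for pk in c.peaks]
    write_narrowpeak(p("ctcf.narrowPeak"), all_peaks)
    paths["ctcf"] = p("ctcf.narrowPeak")
    all_motifs = [m for c in chromosomes.values() for m in c.motifs]
    write_bed(p("motif.bed"), all_motifs)
    paths["motif"] = p("motif.bed")
    for track in ("dnase", "rad21", "polr2a", "h3k4me3", "h3k27ac", "noise"):
        cov = {name: c.tracks[track] for name, c in chromosomes.items()}
        write_bedgraph(p(f"{track}.bedGraph"), cov)
        paths[track] = p(f"{track}.bedGraph")
    for name, c in chromosomes.items():
        mat = c.contact_matrix()
        write_contacts(p(f"contacts_{name}.tsv"), p(f"bins_{name}.tsv"), mat)
        paths[f"contacts_{name}"] = p(f"contacts_{name}.tsv")
        paths[f"bins_{name}"] = p(f"bins_{name}.tsv")
        write_score_map(p(f"truth_scores_{name}.tsv"), c.true_scores)
        paths[f"truth_scores_{name}"] = p(f"truth_scores_{name}.tsv")
    tad_records = [
        Peak(interval=t, name=f"tad_{k}")
        for k, t in enumerate(truth.tads)
    ]
    write_bed(p("truth_tads.bed"), tad_records)
    paths["truth_tads"] = p("truth_tads.bed")
    write_pairs(p("known_pairs.tsv"), truth.planted_known_pairs)
    paths["known_pairs"] = p("known_pairs.tsv")
    with open(p("manifest.json"), "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(cfg), "files": sorted(paths)},
            fh,
            indent=2,
        )
    paths["manifest"] = p("manifest.json")
    return paths, truth


def make_segments(chrom_data: SynthChromosome) -> list[Segment]:
    """Segment + featurize one synthetic chromosome with SYNTH_SCHEMA."""
    segs = segment_by_ctcf(chrom_data.peaks)
    return featurize(segs, chrom_data.tracks, chrom_data.motifs, SYNTH_SCHEMA)


def build_training_dataset(cfg: SynthConfig):
    """Featurized per-chromosome training data paired with true scores.

    Runs the generator in memory, then the package's own segmentation
    and featurization, and returns ({chrom: ChromosomeData}, truth).
    """
    from .training_inference import ChromosomeData

    _, truth = generate(cfg)
    dataset = {}
    for name, c in truth.chromosomes.items():
        segs = make_segments(c)
        dataset[name] = ChromosomeData(
            features=feature_matrix(segs), scores=c.true_scores, chrom=name
        )
    return dataset, truth


def truth_report(truth: SynthTruth) -> dict:
    """Summary counts and score decay by genomic-distance bin."""
    n_segments = sum(c.n_segments for c in truth.chromosomes.values())
    n_tads = sum(len(c.tad_bounds) - 1 for c in truth.chromosomes.values())
    by_bin: dict[str, list[float]] = {"0-1Mb": [], "1-2Mb": [], ">2Mb": []}
    for c in truth.chromosomes.values():
        mids = (c.anchors[:-1] + c.anchors[1:]) / 2.0
        for (i, j), s in c.true_scores.pairs.items():
            d = abs(mids[j] - mids[i])
            if d < 1e6:
                by_bin["0-1Mb"].append(s)
            elif d < 2e6:
                by_bin["1-2Mb"].append(s)
            else:
                by_bin[">2Mb"].append(s)
    return {
        "n_segments": n_segments,
        "n_tads": n_tads,
        "n_known_pairs": len(truth.planted_known_pairs),
        "mean_score_by_distance": {
            k: (float(np.mean(v)) if v else None) for k, v in by_bin.items()
        },
    }
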