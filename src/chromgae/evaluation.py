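"""Evaluation battery: correlation, TAD discrimination, insulation, enrichment.

Predicted segment-pair scores are judged four ways: (i) Pearson
correlation and MSE against the true scores, overall and stratified by
genomic distance; (ii) ROC-AUC for separating within-TAD from
between-adjacent-TAD pairs (rank-sum estimator, ties averaged);
(iii) a per-boundary TAD-separation score — one minus the fraction of
positive (binarized) pairs in the window diamond crossing the boundary;
and (iv) fold-of-enrichment of known interaction pairs above a sweep of
score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .hic_processing import SegmentScoreMap
from .io_formats import GenomicInterval, PairList
from .segmentation import Segment

__all__ = [
    "EvalReport",
    "pcc_mse",
    "stratify_by_distance",
    "tad_auc",
    "separation_score",
    "fold_enrichment",
    "matched_threshold",
]

#: Default binarization threshold for (log1p) truth score maps.
DEFAULT_BINARIZE_THRESHOLD = 1.4


@dataclass
class EvalReport:
    overall_pcc: Optional[float] = None
    overall_mse: Optional[float] = None
    pcc_by_distance: list[tuple[str, Optional[float], int]] = field(
        default_factory=list
    )
    tad_auc: Optional[float] = None
    separation_pcc: Optional[float] = None
    enrichment_curve: list[tuple[float, Optional[float], int]] = field(
        default_factory=list
    )

    def to_dict(self) -> dict:
        return {
            "overall_pcc": self.overall_pcc,
            "overall_mse": self.overall_mse,
            "pcc_by_distance": [list(t) for t in self.pcc_by_distance],
            "tad_auc": self.tad_auc,
            "separation_pcc": self.separation_pcc,
            "enrichment_curve": [list(t) for t in self.enrichment_curve],
        }


def pcc_mse(pred, truth) -> tuple[Optional[float], float]:
    """Pearson r and MSE of paired score vectors (r absent if degenerate)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    mse = float(np.mean((pred - truth) ** 2))
    if np.std(pred) == 0 or np.std(truth) == 0:
        return None, mse
    return float(stats.pearsonr(pred, truth)[0]), mse


def _common_pairs(
    pred_map: SegmentScoreMap, true_map: SegmentScoreMap
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    keys = sorted(set(pred_map.pairs) & set(true_map.pairs))
    p = np.array([pred_map.pairs[k] for k in keys])
    t = np.array([true_map.pairs[k] for k in keys])
    return keys, p, t


def stratify_by_distance(
    pairs: list[tuple[int, int]],
    segments: list[Segment],
    bin_edges: list[float],
) -> dict[str, list[tuple[int, int]]]:
    """Assign pairs to half-open genomic-distance bins [e_k, e_{k+1}).

    Distance is between segment midpoints; ``bin_edges`` are ascending
    and an implicit final edge at +inf closes the last bin. A distance
    exactly at an edge goes to the upper bin.
    """
    edges = list(bin_edges) + [float("inf")]
    mids = {s.index: s.interval.midpoint for s in segments}
    out: dict[str, list[tuple[int, int]]] = {}
    labels = [
        f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])
    ]
    for lab in labels:
        out[lab] = []
    for i, j in pairs:
        d = abs(mids[j] - mids[i])
        k = int(np.searchsorted(np.asarray(edges[1:-1]), d, side="right"))
        out[labels[k]].append((i, j))
    return out


def _tad_of(midpoint: int, tads: list[GenomicInterval]) -> int:
    """Index of the TAD containing the midpoint, or -1."""
    starts = np.array([t.start for t in tads])
    k = int(np.searchsorted(starts, midpoint, side="right")) - 1
    if k >= 0 and midpoint < tads[k].end:
        return k
    return -1


def tad_auc(
    score_map: SegmentScoreMap,
    tads: list[GenomicInterval],
    segments: list[Segment],
) -> tuple[float, np.ndarray]:
    """ROC-AUC for within-TAD vs between-adjacent-TAD pair scores.

    A pair is "within" when both segment midpoints fall in the same TAD
    and "between" when they fall in two adjacent TADs; other pairs are
    excluded. The AUC is the rank-sum (Mann–Whitney) statistic with ties
    averaged; ROC points are returned alongside.
    """
    tads = sorted(tads, key=lambda t: t.start)
    mids = {s.index: s.interval.midpoint for s in segments}
    within, between = [], []
    for (i, j), s in score_map.pairs.items():
        if i not in mids or j not in mids:
            continue
        a, b = _tad_of(mids[i], tads), _tad_of(mids[j], tads)
        if a < 0 or b < 0:
            continue
        if a == b:
            within.append(s)
        elif abs(a - b) == 1:
            between.append(s)
    if not within or not between:
        raise ValueError("one of the within/between classes is empty")
    pos = np.asarray(within)
    neg = np.asarray(between)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores)
    tpr = np.cumsum(labels[order]) / len(pos)
    fpr = np.cumsum(1 - labels[order]) / len(neg)
    roc = np.column_stack([np.concatenate([[0], fpr]), np.concatenate([[0], tpr])])
    return float(auc), roc


def separation_score(
    score_map: SegmentScoreMap,
    n_segments: int,
    window: int = 5,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary TAD-separation scores from a binarized score map.

    Scores are binarized at ``threshold``; for the boundary after
    segment b (between b and b+1) the insulation is the fraction of
    positive pairs among all scored (i, j) with b−window < i ≤ b < j ≤
    b+window — the window diamond crossing the boundary — and the
    separation is 1 − insulation. Returns (scores, complete) where
    ``complete`` flags boundaries whose diamond fits the chromosome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= n_segments:
        raise ValueError("window larger than the chromosome")
    sep = np.full(n_segments - 1, np.nan)
    complete = np.zeros(n_segments - 1, dtype=bool)
    for b in range(n_segments - 1):
        pos = tot = 0
        for i in range(max(0, b - window + 1), b + 1):
            for j in range(b + 1, min(n_segments, b + window + 1)):
                if (i, j) in score_map.pairs:
                    tot += 1
                    if score_map.pairs[(i, j)] >= threshold:
                        pos += 1
        if tot:
            sep[b] = 1.0 - pos / tot
        complete[b] = (b - window + 1 >= 0) and (b + window <= n_segments - 1)
    return sep, complete


def matched_threshold(
    pred_map: SegmentScoreMap,
    true_map: SegmentScoreMap,
    true_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> float:
    """Prediction threshold whose positive rate matches the truth's.

    Quantile matching: the truth's positive fraction at
    ``true_threshold`` picks the same upper quantile of the predicted
    score distribution.
    """
    t = np.array(list(true_map.pairs.values()))
    p = np.array(list(pred_map.pairs.values()))
    rate = float(np.mean(t >= true_threshold))
    if rate <= 0:
        return float(p.max()) + 1.0
    return float(np.quantile(p, 1.0 - rate))


def _pairs_to_segments(
    known: PairList, segments: list[Segment]
) -> set[tuple[int, int]]:
    """Map interval pairs to segment-index pairs by any-overlap of anchors."""
    starts = np.array([s.interval.start for s in segments])
    ends = np.array([s.interval.end for s in segments])
    idx = np.array([s.index for s in segments])
    chrom = segments[0].interval.chrom if segments else None

    def overlapping(iv: GenomicInterval) -> np.ndarray:
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        return idx[lo:hi]

    out: set[tuple[int, int]] = set()
    for a, b, _tag in known.records:
        if chrom is not None and (a.chrom != chrom or b.chrom != chrom):
            continue
        for i in overlapping(a):
            for j in overlapping(b):
                if i != j:
                    out.add((min(i, j), max(i, j)))
    return out


def fold_enrichment(
    score_map: SegmentScoreMap,
    known: PairList,
    segments: list[Segment],
    thresholds: list[float],
) -> list[tuple[float, Optional[float], int]]:
    """Fold-of-enrichment of known pairs above each score threshold.

    FE(t) = [|known ∧ score ≥ t| / |score ≥ t|] ÷ [|known| / |scored|].
    Points with no pair above the threshold are reported with fold
    absent. Known pairs are mapped to segment pairs by any-overlap of
    both anchors.
    """
    known_keys = _pairs_to_segments(known, segments) & set(score_map.pairs)
    all_pairs = list(score_map.pairs.items())
    n_all = len(all_pairs)
    n_known = len(known_keys)
    curve: list[tuple[float, Optional[float], int]] = []
    if n_all == 0 or n_known == 0:
        return [(float(t), None, 0) for t in thresholds]
    base = n_known / n_all
    for t in thresholds:
        above = [k for k, s in all_pairs if s >= t]
        n_above = len(above)
        if n_above == 0:
            curve.append((float(t), None, 0))
            continue
        hit = sum(1 for k in above if k in known_keys)
        curve.append((float(t), (hit / n_above) / base, n_above))
    return curve
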