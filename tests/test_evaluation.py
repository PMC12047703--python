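import numpy as np
import pytest

from chromgae.evaluation import (
    fold_enrichment,
    matched_threshold,
    pcc_mse,
    separation_score,
    stratify_by_distance,
    tad_auc,
)
from chromgae.hic_processing import SegmentScoreMap
from chromgae.io_formats import GenomicInterval, PairList
from chromgae.segmentation import Segment


def _segments(n, length=100_000):
    return [
        Segment(
            interval=GenomicInterval("chr1", k * length, (k + 1) * length),
            index=k,
        )
        for k in range(n)
    ]


class TestPccMse:
    def test_perfect_and_inverted(self, rng):
        x = rng.random(20)
        pcc, mse = pcc_mse(x, x)
        assert pcc == pytest.approx(1.0) and mse == 0.0
        pcc, _ = pcc_mse(-x, x)
        assert pcc == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        a, b = rng.random(200), rng.random(200)
        am, bm = a.mean(), b.mean()
        ref = ((a - am) * (b - bm)).sum() / np.sqrt(
            ((a - am) ** 2).sum() * ((b - bm) ** 2).sum()
        )
        pcc, mse = pcc_mse(a, b)
        assert pcc == pytest.approx(ref, abs=1e-12)
        assert mse == pytest.approx(np.mean((a - b) ** 2), abs=1e-12)

    def test_zero_variance_reports_absent(self):
        pcc, mse = pcc_mse(np.ones(5), np.arange(5.0))
        assert pcc is None and mse > 0


class TestStratifyByDistance:
    def test_edge_goes_to_upper_bin(self):
        segs = _segments(30)
        # midpoints are 100 kb apart; pair (0, 10) is exactly at 1 Mb
        out = stratify_by_distance([(0, 10)], segs, [0, 1e6, 2e6])
        assert [k for k, v in out.items() if v] == ["[1e+06,2e+06)"]

    def test_bins_partition_all_pairs(self, rng):
        segs = _segments(40)
        pairs = [
            (i, j) for i in range(40) for j in range(i + 1, 40)
        ]
        out = stratify_by_distance(pairs, segs, [0, 1e6, 2e6])
        assert sum(len(v) for v in out.values()) == len(pairs)
        flat = [p for v in out.values() for p in v]
        assert sorted(flat) == sorted(pairs)


class TestTadAuc:
    def _tads(self, bounds, length=100_000):
        return [
            GenomicInterval("chr1", a * length, b * length)
            for a, b in zip(bounds, bounds[1:])
        ]

    def test_perfect_separation_gives_auc_one(self):
        segs = _segments(10)
        tads = self._tads([0, 5, 10])
        pairs = {}
        for i in range(10):
            for j in range(i + 1, 10):
                same = (i < 5) == (j < 5)
                pairs[(i, j)] = 2.0 if same else 1.0
        auc, roc = tad_auc(SegmentScoreMap(pairs=pairs), tads, segs)
        assert auc == 1.0
        assert roc[-1].tolist() == [1.0, 1.0]

    def test_all_ties_give_half(self):
        segs = _segments(10)
        tads = self._tads([0, 5, 10])
        pairs = {(i, j): 1.0 for i in range(10) for j in range(i + 1, 10)}
        auc, _ = tad_auc(SegmentScoreMap(pairs=pairs), tads, segs)
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_concordance(self, rng):
        segs = _segments(16)
        tads = self._tads([0, 4, 9, 16])
        pairs = {
            (i, j): float(rng.random())
            for i in range(16)
            for j in range(i + 1, 16)
        }
        sm = SegmentScoreMap(pairs=pairs)
        auc, _ = tad_auc(sm, tads, segs)
        # brute force: P(within > between) + 0.5 P(tie)
        tad_of = lambda k: 0 if k < 4 else (1 if k < 9 else 2)
        within = [s for (i, j), s in pairs.items() if tad_of(i) == tad_of(j)]
        between = [
            s
            for (i, j), s in pairs.items()
            if abs(tad_of(i) - tad_of(j)) == 1
        ]
        num = sum(
            1.0 if w > b else (0.5 if w == b else 0.0)
            for w in within
            for b in between
        )
        assert auc == pytest.approx(num / (len(within) * len(between)))

    def test_empty_class_is_error(self):
        segs = _segments(4)
        tads = self._tads([0, 4])
        pairs = {(0, 1): 1.0, (2, 3): 2.0}
        with pytest.raises(ValueError, match="empty"):
            tad_auc(SegmentScoreMap(pairs=pairs), tads, segs)


class TestSeparationScore:
    def _block_map(self, n, split, hi=2.0, lo=0.0):
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < split) == (j < split)
                pairs[(i, j)] = hi if same else lo
        return SegmentScoreMap(pairs=pairs)

    def test_peak_at_block_boundary(self):
        sm = self._block_map(12, 6)
        sep, complete = separation_score(sm, 12, window=3, threshold=1.0)
        assert np.nanargmax(sep) == 5  # boundary between segments 5 and 6
        assert sep[5] == 1.0

    def test_all_positive_map_gives_zero(self):
        sm = self._block_map(8, 4, hi=2.0, lo=2.0)
        sep, _ = separation_score(sm, 8, window=2, threshold=1.0)
        assert np.allclose(sep[~np.isnan(sep)], 0.0)

    def test_all_negative_map_gives_one(self):
        sm = self._block_map(8, 4, hi=0.5, lo=0.5)
        sep, _ = separation_score(sm, 8, window=2, threshold=1.0)
        assert np.allclose(sep[~np.isnan(sep)], 1.0)

    def test_incomplete_windows_flagged(self):
        sm = self._block_map(10, 5)
        _, complete = separation_score(sm, 10, window=3, threshold=1.0)
        assert not complete[0] and not complete[-1]
        assert complete[4]

    def test_window_larger_than_chromosome_is_error(self):
        sm = self._block_map(4, 2)
        with pytest.raises(ValueError):
            separation_score(sm, 4, window=10)


class TestFoldEnrichment:
    def _known(self, segs, keys):
        return PairList(
            records=[
                (segs[i].interval, segs[j].interval, "known") for i, j in keys
            ]
        )

    def test_known_everything_gives_unity(self, rng):
        segs = _segments(8)
        pairs = {
            (i, j): float(rng.random()) for i in range(8) for j in range(i + 1, 8)
        }
        known = self._known(segs, list(pairs))
        curve = fold_enrichment(
            SegmentScoreMap(pairs=pairs), known, segs, [0.0, 0.5]
        )
        for _t, fold, n in curve:
            if n:
                assert fold == pytest.approx(1.0)

    def test_top_scored_known_pairs_enrich_monotonically(self):
        segs = _segments(10)
        pairs = {}
        v = 0.0
        keys = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        for k in keys:
            pairs[k] = v
            v += 1.0
        known_keys = keys[-5:]  # the five top-scoring pairs
        curve = fold_enrichment(
            SegmentScoreMap(pairs=pairs),
            self._known(segs, known_keys),
            segs,
            [0.0, 20.0, 40.0],
        )
        folds = [f for _t, f, _n in curve]
        assert folds[0] < folds[1] < folds[2]

    def test_hand_computed_ratio(self):
        segs = _segments(5)
        pairs = {
            (0, 1): 3.0,
            (0, 2): 2.0,
            (1, 2): 1.0,
            (2, 3): 0.5,
            (3, 4): 0.1,
        }
        known = self._known(segs, [(0, 1), (2, 3)])
        (t, fold, n), = fold_enrichment(
            SegmentScoreMap(pairs=pairs), known, segs, [1.5]
        )
        # above 1.5: {(0,1),(0,2)}; known among them: 1 of 2; base 2 of 5
        assert n == 2
        assert fold == pytest.approx((1 / 2) / (2 / 5))

    def test_minimum_threshold_gives_unity(self, rng):
        segs = _segments(6)
        pairs = {
            (i, j): float(rng.random()) for i in range(6) for j in range(i + 1, 6)
        }
        known = self._known(segs, [(0, 1), (4, 5)])
        curve = fold_enrichment(
            SegmentScoreMap(pairs=pairs), known, segs, [min(pairs.values())]
        )
        assert curve[0][1] == pytest.approx(1.0)


def test_matched_threshold_matches_positive_rate(rng):
    truth = SegmentScoreMap(
        pairs={(0, k): float(v) for k, v in enumerate(rng.random(1000) * 3, 1)}
    )
    pred = SegmentScoreMap(
        pairs={(0, k): float(v) for k, v in enumerate(rng.random(1000) * 5, 1)}
    )
    t = matched_threshold(pred, truth, true_threshold=1.4)
    rate_t = np.mean([v >= 1.4 for v in truth.pairs.values()])
    rate_p = np.mean([v >= t for v in pred.pairs.values()])
    assert rate_p == pytest.approx(rate_t, abs=0.01)
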