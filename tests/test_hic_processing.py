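import numpy as np
import pytest

from chromgae.hic_processing import (
    SegmentScoreMap,
    ice,
    kr,
    read_score_map,
    segment_scores,
    sqrtvc,
    write_score_map,
)
from chromgae.io_formats import ContactMatrix, GenomicInterval
from chromgae.segmentation import Segment


def _random_symmetric(n, rng, positive=True):
    raw = rng.random((n, n)) + (0.1 if positive else 0.0)
    return (raw + raw.T) / 2


class TestSqrtvc:
    def test_hand_oracle_2x2(self):
        # row sums (4, 4): every entry 2/sqrt(16) = 0.5
        out = sqrtvc(np.array([[2.0, 2.0], [2.0, 2.0]]))
        assert np.allclose(out, 0.5)

    def test_all_zero_matrix_unchanged(self):
        assert np.array_equal(sqrtvc(np.zeros((3, 3))), np.zeros((3, 3)))

    def test_symmetry_preserved(self, rng):
        out = sqrtvc(_random_symmetric(15, rng))
        assert np.allclose(out, out.T)

    def test_zero_row_left_as_zero(self, rng):
        m = _random_symmetric(6, rng)
        m[2, :] = m[:, 2] = 0.0
        out = sqrtvc(m)
        assert np.all(out[2] == 0) and np.all(np.isfinite(out))


class TestIce:
    def test_equal_row_sums_is_fixed_point(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        out = ice(m)
        assert np.allclose(out / out.max(), m / m.max())
        assert out.converged

    def test_row_sums_equalized_random_20x20(self, rng):
        out = ice(_random_symmetric(20, rng), tol=1e-6)
        r = np.asarray(out).sum(axis=1)
        assert np.max(np.abs(r / r.mean() - 1)) < 1e-6
        assert out.converged

    def test_masked_zero_rows_restored_as_zero(self, rng):
        m = _random_symmetric(10, rng)
        m[4, :] = m[:, 4] = 0.0
        out = np.asarray(ice(m))
        assert np.all(out[4] == 0)
        r = np.delete(out, 4, axis=0).sum(axis=1)
        assert np.max(np.abs(r / r.mean() - 1)) < 1e-5


class TestKr:
    def test_diagonal_closed_form(self):
        # x = 1/sqrt(diag): diag(4) balances to the identity
        out = kr(np.diag([4.0, 4.0, 4.0]))
        assert np.allclose(out, np.eye(3), atol=1e-8)

    def test_doubly_stochastic_fixed_point(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(kr(m), m, atol=1e-8)

    def test_row_sums_unit_random_20x20(self, rng):
        out = kr(_random_symmetric(20, rng), tol=1e-8)
        assert np.allclose(np.asarray(out).sum(axis=1), 1.0, atol=1e-6)

    def test_symmetry_and_nonnegativity(self, rng):
        out = np.asarray(kr(_random_symmetric(12, rng)))
        assert np.allclose(out, out.T)
        assert np.all(out >= 0)


def test_ice_and_kr_agree_on_balanced_row_sums(rng):
    """Both balancers equalize visibility; KR additionally fixes scale 1."""
    m = _random_symmetric(20, rng)
    r_ice = np.asarray(ice(m, tol=1e-8)).sum(axis=1)
    r_kr = np.asarray(kr(m, tol=1e-10)).sum(axis=1)
    assert np.max(np.abs(r_ice / r_ice.mean() - 1)) < 1e-6
    assert np.allclose(r_kr, 1.0, atol=1e-7)


def _segments(bounds):
    return [
        Segment(interval=GenomicInterval("chr1", a, b), index=k)
        for k, (a, b) in enumerate(zip(bounds, bounds[1:]))
    ]


def _matrix(values, bin_size=10):
    n = len(values)
    bins = [
        GenomicInterval("chr1", i * bin_size, (i + 1) * bin_size) for i in range(n)
    ]
    return ContactMatrix(bins=bins, values=np.asarray(values, dtype=float))


class TestSegmentScores:
    def test_mean_over_bin_pairs_hand_oracle(self):
        # segment i covers bins {0,1}, j covers bin {2}; mean(M02, M12) = 3
        vals = np.zeros((3, 3))
        vals[0, 2] = vals[2, 0] = 2.0
        vals[1, 2] = vals[2, 1] = 4.0
        mat = _matrix(vals)
        segs = _segments([0, 20, 30])
        sm = segment_scores(mat, segs, max_span=4, log_transform=False)
        assert sm.pairs[(0, 1)] == pytest.approx(3.0)

    def test_pairs_beyond_span_absent(self):
        mat = _matrix(np.ones((6, 6)))
        segs = _segments([0, 10, 20, 30, 40, 50, 60])
        sm = segment_scores(mat, segs, max_span=2, log_transform=False)
        assert (0, 3) not in sm.pairs and (0, 2) in sm.pairs

    def test_deterministic(self):
        mat = _matrix(np.arange(16, dtype=float).reshape(4, 4) + np.arange(16).reshape(4, 4).T)
        segs = _segments([0, 10, 20, 30, 40])
        a = segment_scores(mat, segs, max_span=3)
        b = segment_scores(mat, segs, max_span=3)
        assert a.pairs == b.pairs

    def test_scale_equivariance_before_log(self, rng):
        vals = _random_symmetric(8, rng)
        segs = _segments([0, 20, 40, 60, 80])
        a = segment_scores(_matrix(vals), segs, max_span=4, log_transform=False)
        b = segment_scores(_matrix(3.0 * vals), segs, max_span=4, log_transform=False)
        for k in a.pairs:
            assert b.pairs[k] == pytest.approx(3.0 * a.pairs[k])

    def test_uncovered_segment_flagged(self):
        vals = np.ones((2, 2))
        mat = _matrix(vals)
        segs = _segments([0, 10, 20, 500, 600])
        sm = segment_scores(mat, segs, max_span=4)
        assert 2 in sm.uncovered_segments or 3 in sm.uncovered_segments

    def test_log_transform_applied_after_mean(self, rng):
        vals = _random_symmetric(6, rng)
        segs = _segments([0, 20, 40, 60])
        raw = segment_scores(_matrix(vals), segs, max_span=3, log_transform=False)
        logd = segment_scores(_matrix(vals), segs, max_span=3, log_transform=True)
        for k in raw.pairs:
            assert logd.pairs[k] == pytest.approx(np.log1p(raw.pairs[k]))


def test_score_map_round_trip(tmp_path, rng):
    sm = SegmentScoreMap(
        pairs={(i, j): float(rng.random()) for i in range(10) for j in range(i + 1, 10)},
        normalization="SQRTVC",
        log_transformed=True,
    )
    write_score_map(tmp_path / "s.tsv", sm)
    back = read_score_map(tmp_path / "s.tsv")
    assert back.pairs == sm.pairs
    assert back.normalization == "SQRTVC" and back.log_transformed
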