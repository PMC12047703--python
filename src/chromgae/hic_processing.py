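"""Contact-matrix balancing and segment-pair interaction scores.

Three balancing schemes are provided. SQRTVC divides each entry by the
square roots of its row and column sums. ICE iteratively divides by a
bias vector until all (unmasked) bins are equally visible. KR computes a
positive scaling vector x with diag(x)·M·diag(x) doubly stochastic via
the Knight–Ruiz inner–outer Newton iteration. Rows whose sum is zero are
masked out and restored as zero by all three.

Segment-pair scores (the model's edge labels) are the mean of the
normalized matrix over all bin pairs overlapping the two segments,
optionally log1p-compressed, restricted to index separations within the
model's span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ContactMatrix, GenomicInterval
from .segmentation import Segment

__all__ = [
    "SegmentScoreMap",
    "sqrtvc",
    "ice",
    "kr",
    "KRBreakdownError",
    "segment_scores",
    "write_score_map",
    "read_score_map",
]


@dataclass
class SegmentScoreMap:
    """Map (i, j) with i < j → interaction score between segments i and j."""

    pairs: dict[tuple[int, int], float] = field(default_factory=dict)
    normalization: str = "none"
    log_transformed: bool = False
    converged: bool = True
    uncovered_segments: tuple[int, ...] = ()

    def get(self, i: int, j: int, default: float = 0.0) -> float:
        if i == j:
            raise KeyError("self-pairs are not scored")
        key = (i, j) if i < j else (j, i)
        return self.pairs.get(key, default)

    def __len__(self) -> int:
        return len(self.pairs)


class KRBreakdownError(RuntimeError):
    """KR iterate left the positive cone; use ICE as a fallback."""


def _as_array(matrix) -> tuple[np.ndarray, ContactMatrix | None]:
    if isinstance(matrix, ContactMatrix):
        return matrix.values.astype(float, copy=True), matrix
    return np.asarray(matrix, dtype=float).copy(), None


def _wrap(values: np.ndarray, template: ContactMatrix | None):
    if template is None:
        return values
    return ContactMatrix(bins=template.bins, values=values)


def sqrtvc(matrix):
    """Square-root vanilla-coverage balancing: M'_ij = M_ij / sqrt(r_i r_j)."""
    M, template = _as_array(matrix)
    r = M.sum(axis=1)
    scale = np.sqrt(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(scale > 0, 1.0 / scale, 0.0)
    out = M * inv[:, None] * inv[None, :]
    return _wrap(out, template)


def ice(matrix, tol: float = 1e-6, max_iter: int = 200):
    """Iterative correction: divide by row-sum biases until equal visibility.

    The bias vector is renormalized to mean 1 over unmasked bins each
    iteration to fix the arbitrary overall scale. Returns the balanced
    matrix; on a ContactMatrix input the result carries the bins, and a
    ``converged`` attribute is attached in both cases.
    """
    M, template = _as_array(matrix)
    mask = M.sum(axis=1) > 0
    converged = True
    if mask.any():
        sub = M[np.ix_(mask, mask)]
        for _ in range(max_iter):
            r = sub.sum(axis=1)
            b = r / r.mean()
            sub /= np.outer(b, b)
            r_new = sub.sum(axis=1)
            dev = np.max(np.abs(r_new / r_new.mean() - 1.0))
            if dev < tol:
                break
        else:
            converged = False
        M[np.ix_(mask, mask)] = sub
        M[~mask, :] = 0.0
        M[:, ~mask] = 0.0
    out = _wrap(M, template)
    if template is None:
        out = out.view(_FlaggedArray)
    out.converged = converged
    return out


class _FlaggedArray(np.ndarray):
    """ndarray subclass carrying the ICE convergence flag."""

    converged: bool = True


def kr(matrix, tol: float = 1e-8, max_iter: int = 100):
    """Knight–Ruiz balancing to a doubly stochastic matrix.

    Finds x > 0 with diag(x)·M·diag(x) having unit row sums, using the
    inner–outer Newton iteration with conjugate-gradient inner solves.
    Zero-sum rows are masked and restored as zero.
    """
    M, template = _as_array(matrix)
    mask = M.sum(axis=1) > 0
    if mask.any():
        A = M[np.ix_(mask, mask)]
        x = _kr_vector(A, tol=tol, max_iter=max_iter)
        M[np.ix_(mask, mask)] = A * np.outer(x, x)
        M[~mask, :] = 0.0
        M[:, ~mask] = 0.0
    return _wrap(M, template)


def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Inner–outer Newton iteration of Knight & Ruiz for e-row-sum balance."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    i = 0
    while rout > rt and i < max_iter:
        i += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 10 * n:
                break
        x = x * y
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise KRBreakdownError(
                "KR iterate left the positive cone; the matrix may not be "
                "fully indecomposable — consider ICE balancing instead"
            )
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, g * etamax), 0.5)
        etamax = eta
        _ = res_norm
    return x


# ---------------------------------------------------------------------------
# segment scores


def _segment_bin_ranges(
    segments: list[Segment], bins: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """Half-open bin-index range overlapping each segment (any-overlap)."""
    bin_starts = np.array([b.start for b in bins])
    bin_ends = np.array([b.end for b in bins])
    out = []
    for seg in segments:
        lo = int(np.searchsorted(bin_ends, seg.interval.start, side="right"))
        hi = int(np.searchsorted(bin_starts, seg.interval.end, side="left"))
        out.append((lo, hi))
    return out


def segment_scores(
    matrix: ContactMatrix,
    segments: list[Segment],
    max_span: int = 64,
    log_transform: bool = True,
    normalization: str = "none",
) -> SegmentScoreMap:
    """Aggregate bin-level contacts into segment-pair edge labels.

    score(i, j) is the mean matrix value over all bin pairs (a, b) with
    bin a overlapping segment i and bin b overlapping segment j (>= 1 bp
    overlap), computed for 1 <= j - i <= max_span; with ``log_transform``
    the score is log1p-compressed. Segments overlapping no bin are
    reported in ``uncovered_segments``.
    """
    ranges = _segment_bin_ranges(segments, matrix.bins)
    uncovered = tuple(
        seg.index for seg, (lo, hi) in zip(segments, ranges) if hi <= lo
    )
    M = matrix.values
    pairs: dict[tuple[int, int], float] = {}
    for a, seg_i in enumerate(segments):
        lo_i, hi_i = ranges[a]
        if hi_i <= lo_i:
            continue
        for b in range(a + 1, min(a + max_span, len(segments) - 1) + 1):
            lo_j, hi_j = ranges[b]
            if hi_j <= lo_j:
                continue
            score = float(M[lo_i:hi_i, lo_j:hi_j].mean())
            if log_transform:
                score = float(np.log1p(score))
            pairs[(segments[a].index, segments[b].index)] = score
    return SegmentScoreMap(
        pairs=pairs,
        normalization=normalization,
        log_transformed=log_transform,
        uncovered_segments=uncovered,
    )


def write_score_map(path, score_map: SegmentScoreMap) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# normalization={score_map.normalization} "
            f"log_transformed={score_map.log_transformed}\n"
        )
        for (i, j), s in sorted(score_map.pairs.items()):
            fh.write(f"{i}\t{j}\t{s!r}\n")


def read_score_map(path) -> SegmentScoreMap:
    pairs: dict[tuple[int, int], float] = {}
    normalization, log_transformed = "none", False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("normalization="):
                        normalization = token.split("=", 1)[1]
                    elif token.startswith("log_transformed="):
                        log_transformed = token.split("=", 1)[1] == "True"
                continue
            if not line:
                continue
            i, j, s = line.split("\t")
            pairs[(int(i), int(j))] = float(s)
    return SegmentScoreMap(
        pairs=pairs, normalization=normalization, log_transformed=log_transformed
    )
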