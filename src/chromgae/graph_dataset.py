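"""Subgraph construction: windows, restricted random edges, signed weights.

Training graphs are 128-segment windows cropped (with replacement) from a
chromosome. Vertices closer than the maximal span (64 segments) are
connected independently with probability 0.5 — a restricted Erdős–Rényi
G(128, 0.5) — while pairs beyond the span are never connected. Every edge
carries a signed distance weight ω = ln(d / flip_range): negative inside
the cis-interaction range (d < 9 segments by default), zero at the range,
positive beyond it. At inference the edge set is the deterministic
all-pairs-within-span graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hic_processing import SegmentScoreMap

__all__ = [
    "SamplerConfig",
    "SegmentGraph",
    "crop_windows",
    "sample_edges",
    "all_edges",
    "signed_weight",
    "assemble",
    "merge_graphs",
]


@dataclass(frozen=True)
class SamplerConfig:
    subgraph_size: int = 128
    max_span: int = 64
    edge_prob: float = 0.5
    flip_range: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_span < self.subgraph_size):
            raise ValueError("require 0 < max_span < subgraph_size")
        if not (0 < self.edge_prob <= 1):
            raise ValueError("require 0 < edge_prob <= 1")
        if self.flip_range < 1:
            raise ValueError("require flip_range >= 1")


@dataclass
class SegmentGraph:
    """A window of consecutive segments with its (sampled) edge set.

    ``edges`` holds local undirected index pairs (i, j), i < j, with
    signed weight ``edge_weight`` per edge and, in training mode, the
    looked-up interaction score in ``edge_label``.
    """

    chrom: str
    first_index: int
    size: int
    node_features: np.ndarray
    edges: np.ndarray  # (E, 2) int, i < j
    edge_weight: np.ndarray  # (E,) float
    edge_label: Optional[np.ndarray] = None  # (E,) float or None at inference

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if len(e):
            d = np.abs(e[:, 0] - e[:, 1])
            if d.min() < 1:
                raise ValueError("self-edges are not allowed")
        if not np.all(np.isfinite(self.edge_weight)):
            raise ValueError("edge weights must be finite")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def crop_windows(
    n_segments: int,
    cfg: SamplerConfig,
    n_windows: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw window starts uniformly with replacement."""
    if n_segments < cfg.subgraph_size:
        raise ValueError(
            f"chromosome with {n_segments} segments is shorter than one "
            f"window of {cfg.subgraph_size}"
        )
    return rng.integers(0, n_segments - cfg.subgraph_size + 1, size=n_windows)


def _eligible_pairs(size: int, max_span: int) -> np.ndarray:
    """All (i, j) with i < j and j - i <= max_span, lexicographic order."""
    i, j = np.triu_indices(size, k=1)
    keep = (j - i) <= max_span
    return np.column_stack([i[keep], j[keep]])


def sample_edges(cfg: SamplerConfig, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(edge_prob) sample of the within-span pairs of a window."""
    pairs = _eligible_pairs(cfg.subgraph_size, cfg.max_span)
    if cfg.edge_prob >= 1.0:
        return pairs
    keep = rng.random(len(pairs)) < cfg.edge_prob
    return pairs[keep]


def all_edges(cfg: SamplerConfig) -> np.ndarray:
    """Deterministic inference edge set: every pair within the span."""
    return _eligible_pairs(cfg.subgraph_size, cfg.max_span)


def signed_weight(i, j, flip_range: int = 9):
    """ω = ln(|i − j| / flip_range); sign flips at the cis-interaction range."""
    i = np.asarray(i)
    j = np.asarray(j)
    d = np.abs(i - j)
    if np.any(d == 0):
        raise ValueError("self-edges have no signed weight")
    w = np.log(d / float(flip_range))
    return float(w) if w.ndim == 0 else w


def assemble(
    window_start: int,
    features: np.ndarray,
    score_map: Optional[SegmentScoreMap],
    cfg: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    mode: str = "train",
    chrom: str = "chr",
) -> SegmentGraph:
    """Build one training or inference subgraph.

    ``features`` is the full per-chromosome (n × 14) matrix; the window
    is ``cfg.subgraph_size`` rows starting at ``window_start``. In train
    mode edges are sampled and labels looked up (absent pairs → 0); in
    infer mode the edge set is all pairs within the span, labels absent.
    """
    size = cfg.subgraph_size
    if window_start < 0 or window_start + size > len(features):
        raise ValueError(
            f"window [{window_start}, {window_start + size}) outside the "
            f"featurized chromosome of {len(features)} segments"
        )
    X = np.asarray(features[window_start : window_start + size], dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("window features contain non-finite entries")
    if mode == "train":
        if rng is None:
            raise ValueError("train mode needs an rng")
        edges = sample_edges(cfg, rng)
        if score_map is None:
            raise ValueError("train mode needs a score map")
        labels = np.array(
            [
                score_map.get(window_start + i, window_start + j, 0.0)
                for i, j in edges
            ]
        )
    elif mode == "infer":
        edges = all_edges(cfg)
        labels = None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    weights = signed_weight(edges[:, 0], edges[:, 1], cfg.flip_range)
    return SegmentGraph(
        chrom=chrom,
        first_index=window_start,
        size=size,
        node_features=X,
        edges=edges,
        edge_weight=np.atleast_1d(weights),
        edge_label=labels,
    )


def merge_graphs(graphs: list[SegmentGraph]) -> SegmentGraph:
    """Stack subgraphs into one block-diagonal batch graph.

    Node features are concatenated and edge indices offset so the
    windows stay disconnected; message passing over the merged graph is
    exactly message passing over each window separately.
    """
    if not graphs:
        raise ValueError("no graphs to merge")
    offsets = np.cumsum([0] + [g.size for g in graphs[:-1]])
    edges = np.vstack([g.edges + off for g, off in zip(graphs, offsets)])
    labels = None
    if all(g.edge_label is not None for g in graphs):
        labels = np.concatenate([g.edge_label for g in graphs])
    return SegmentGraph(
        chrom="+".join(dict.fromkeys(g.chrom for g in graphs)),
        first_index=graphs[0].first_index,
        size=int(sum(g.size for g in graphs)),
        node_features=np.vstack([g.node_features for g in graphs]),
        edges=edges,
        edge_weight=np.concatenate([g.edge_weight for g in graphs]),
        edge_label=labels,
    )
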