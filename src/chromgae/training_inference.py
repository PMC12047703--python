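"""Leave-one-chromosome-out training and whole-chromosome prediction.

Training minimizes the MSE between decoded inner products and the
segment-pair interaction scores over randomly cropped 128-segment
windows of the training chromosomes, with a fresh Erdős–Rényi edge set
resampled for every window (a training-time regularizer). Evaluation on
a test chromosome never reuses training chromosomes: each autosome in
turn is held out, mirroring a leave-one-out design over chromosomes.

Whole-chromosome prediction tiles the chromosome with half-overlapping
windows, infers each window on the deterministic all-pairs-within-span
edge set, and averages predictions for pairs covered by several windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .graph_dataset import (
    SamplerConfig,
    all_edges,
    assemble,
    crop_windows,
    merge_graphs,
)
from .hic_processing import SegmentScoreMap
from .model_core import Adam, EncoderParams, decode, encode, loss_and_pred

__all__ = [
    "TrainConfig",
    "FoldSpec",
    "ChromosomeData",
    "leave_one_out",
    "train",
    "predict_map",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 8
    learning_rate: float = 1e-2
    lr_schedule: str = "cosine"
    lr_final: float = 1e-3
    weight_decay: float = 0.05
    optimizer: str = "adam"
    seed: int = 0
    windows_per_epoch: int = 32

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass(frozen=True)
class FoldSpec:
    train_chroms: tuple[str, ...]
    test_chrom: str


@dataclass
class ChromosomeData:
    """Featurized chromosome: feature matrix plus its score map."""

    features: np.ndarray
    scores: SegmentScoreMap
    chrom: str = "chr"


def leave_one_out(chroms: list[str]) -> list[FoldSpec]:
    """One fold per chromosome: fold k tests chrom k, trains on the rest."""
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes")
    if len(set(chroms)) != len(chroms):
        raise ValueError("duplicate chromosome names")
    return [
        FoldSpec(
            train_chroms=tuple(c for c in chroms if c != test),
            test_chrom=test,
        )
        for test in chroms
    ]


def _sample_graphs(
    dataset: dict[str, ChromosomeData],
    chroms: tuple[str, ...],
    cfg: SamplerConfig,
    n: int,
    rng: np.random.Generator,
):
    graphs = []
    picks = rng.choice(len(chroms), size=n)
    for c in picks:
        data = dataset[chroms[c]]
        start = int(crop_windows(len(data.features), cfg, 1, rng)[0])
        graphs.append(
            assemble(start, data.features, data.scores, cfg, rng, "train",
                     chrom=data.chrom)
        )
    return graphs


def _metrics(pred: np.ndarray, label: np.ndarray) -> tuple[float, Optional[float]]:
    """Pooled MSE and Pearson r over labeled edges."""
    mse = float(np.mean((pred - label) ** 2))
    if np.std(pred) == 0 or np.std(label) == 0:
        return mse, None
    return mse, float(stats.pearsonr(pred, label)[0])


def _eval_graphs(graphs, params) -> tuple[float, Optional[float]]:
    merged = merge_graphs(graphs)
    z = encode(merged, params)
    return _metrics(decode(z, merged.edges), merged.edge_label)


def train(
    dataset: dict[str, ChromosomeData],
    fold: FoldSpec,
    cfg: TrainConfig,
    sampler: Optional[SamplerConfig] = None,
    eval_windows: int = 4,
) -> tuple[EncoderParams, list[dict]]:
    """Fit the autoencoder on the fold's training chromosomes.

    Each epoch draws ``windows_per_epoch`` fresh training subgraphs
    (new crops, new random edges) and takes one Adam step per
    ``batch_size`` of them on the summed window losses. The history
    records per-epoch train/test loss and Pearson correlation, the test
    metrics on a fixed set of held-out windows. Deterministic given the
    seed.
    """
    sampler = sampler or SamplerConfig(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    params = EncoderParams.init(rng)
    opt = Adam(
        params.tensors(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )

    test_graphs = []
    if fold.test_chrom in dataset:
        test_rng = np.random.default_rng(cfg.seed + 1)
        test_graphs = _sample_graphs(
            dataset, (fold.test_chrom,), sampler, eval_windows, test_rng
        )

    steps_per_epoch = max(
        1, -(-cfg.windows_per_epoch // cfg.batch_size)
    )
    total_steps = cfg.epochs * steps_per_epoch
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        graphs = _sample_graphs(
            dataset, fold.train_chroms, sampler, cfg.windows_per_epoch, rng
        )
        losses, preds, labels = [], [], []
        for lo in range(0, len(graphs), cfg.batch_size):
            batch = merge_graphs(graphs[lo : lo + cfg.batch_size])
            if cfg.lr_schedule == "cosine":
                frac = min(opt.t / max(total_steps - 1, 1), 1.0)
                opt.lr = cfg.lr_final + 0.5 * (
                    cfg.learning_rate - cfg.lr_final
                ) * (1.0 + np.cos(np.pi * frac))
            opt.zero_grad()
            loss, pred = loss_and_pred(batch, params)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(batch.edges))
            preds.append(pred)
            labels.append(batch.edge_label)
        pred = np.concatenate(preds)
        label = np.concatenate(labels)
        _, train_pcc = _metrics(pred, label)
        record = {
            "epoch": epoch,
            "train_loss": float(sum(losses) / len(pred)),
            "train_pcc": train_pcc,
        }
        if test_graphs:
            test_mse, test_pcc = _eval_graphs(test_graphs, params)
            record["test_loss"] = test_mse
            record["test_pcc"] = test_pcc
        history.append(record)
    return params, history


def predict_map(
    features: np.ndarray,
    params: EncoderParams,
    cfg: Optional[SamplerConfig] = None,
    stride: int = 64,
) -> SegmentScoreMap:
    """Predict every segment pair within the span by window tiling.

    Windows of ``cfg.subgraph_size`` are placed every ``stride``
    segments (the last window is right-aligned so coverage is complete);
    pairs covered by several windows get the mean of their predictions.
    A chromosome shorter than one window is padded with zero-feature
    segments and the padding is dropped from the output.
    """
    cfg = cfg or SamplerConfig()
    size = cfg.subgraph_size
    if stride < 1 or stride > size:
        raise ValueError("require 1 <= stride <= subgraph_size")
    n = len(features)
    features = np.asarray(features, dtype=float)
    padded = False
    if n < size:
        features = np.vstack([features, np.zeros((size - n, features.shape[1]))])
        padded = True
    starts = list(range(0, len(features) - size + 1, stride))
    if starts[-1] != len(features) - size:
        starts.append(len(features) - size)
    edges = all_edges(cfg)
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for start in starts:
        g = assemble(start, features, None, cfg, mode="infer")
        z = encode(g, params)
        scores = decode(z, edges)
        for (i, j), s in zip(edges, scores):
            key = (start + int(i), start + int(j))
            sums[key] = sums.get(key, 0.0) + float(s)
            counts[key] = counts.get(key, 0) + 1
    pairs = {
        k: sums[k] / counts[k]
        for k in sums
        if not padded or (k[0] < n and k[1] < n)
    }
    out = SegmentScoreMap(pairs=pairs, normalization="predicted",
                          log_transformed=True)
    out.padded = padded  # type: ignore[attr-defined]
    return out
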