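"""Interpretability: feature masks, embedding correlations, segment types.

Feature importance follows the learned-mask idea: a sigmoid mask m over
the 14 input features is trained so that encoding the masked features
reproduces the full model's decoded scores, under L1 sparsity and
mask-entropy penalties — features whose mask survives the pressure are
the ones the trained model relies on. Embedding dimensions are related
back to input features by Pearson correlation across segments, and the
segments themselves are stratified into two types by k-means on the top
two kernel principal components of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import KernelPCA

from .autodiff import Tensor, constant, parameter
from .graph_dataset import SegmentGraph
from .model_core import Adam, Embedding, EncoderParams, encode_features

__all__ = [
    "ImportanceReport",
    "feature_importance",
    "embedding_feature_correlation",
    "cluster_segments",
]

N_FEATURES = 14


@dataclass
class ImportanceReport:
    """Learned per-feature mask values in [0, 1] (higher = more important)."""

    mask: np.ndarray
    feature_names: Optional[tuple[str, ...]] = None
    final_loss: float = float("nan")

    def ranking(self) -> np.ndarray:
        """Feature indices sorted from most to least important."""
        return np.argsort(-self.mask)


def _decode_tensor(z: Tensor, pairs: np.ndarray) -> Tensor:
    zi = z.gather(pairs[:, 0])
    zj = z.gather(pairs[:, 1])
    return (zi * zj).sum(axis=1)


def feature_importance(
    params: EncoderParams,
    graphs: list[SegmentGraph],
    epochs: int = 200,
    l1: float = 0.01,
    ent: float = 0.1,
    lr: float = 0.05,
    seed: int = 0,
    feature_names: Optional[tuple[str, ...]] = None,
) -> ImportanceReport:
    """Learn the input-feature mask m = sigmoid(θ) by gradient descent.

    Minimizes, over the given graphs, the MSE between decoded scores of
    the masked input X⊙m and the fixed decoded scores of the full input,
    plus l1·‖m‖₁ and ent·H(m) (elementwise binary entropy). Model
    parameters stay frozen; the mask is the only trainable object.
    Deterministic for a fixed seed.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    rng = np.random.default_rng(seed)
    theta = parameter(rng.normal(0.0, 0.1, size=N_FEATURES))
    opt = Adam([theta], lr=lr)

    targets = []
    for g in graphs:
        z = encode_features(
            constant(g.node_features), g.edges, g.edge_weight, params
        )
        targets.append(_decode_tensor(z, g.edges).data.copy())

    loss_val = float("nan")
    for _ in range(epochs):
        opt.zero_grad()
        m = theta.sigmoid()
        total = None
        for g, target in zip(graphs, targets):
            Xm = constant(g.node_features) * m
            z = encode_features(Xm, g.edges, g.edge_weight, params)
            pred = _decode_tensor(z, g.edges)
            fit = (pred - constant(target)).square().mean()
            total = fit if total is None else total + fit
        total = total * (1.0 / len(graphs))
        one_minus = constant(np.ones(N_FEATURES)) - m
        entropy = -(m * m.log() + one_minus * one_minus.log()).sum()
        total = total + m.sum() * l1 + entropy * ent
        if not np.isfinite(total.data):
            raise FloatingPointError("explainer loss is non-finite")
        total.backward()
        opt.step()
        loss_val = float(total.data)

    mask = 1.0 / (1.0 + np.exp(-theta.data))
    return ImportanceReport(
        mask=mask, feature_names=feature_names, final_loss=loss_val
    )


def embedding_feature_correlation(z, X: np.ndarray) -> np.ndarray:
    """Pearson r between every embedding dimension and every feature.

    Returns a 32 × 14 matrix; entries for constant columns are NaN
    (absent). Rows of ``z`` and ``X`` must describe the same segments.
    """
    zz = z.z if isinstance(z, Embedding) else np.asarray(z, dtype=float)
    X = np.asarray(X, dtype=float)
    if zz.shape[0] != X.shape[0]:
        raise ValueError("embedding and feature matrix rows are not aligned")
    if zz.shape[0] < 3:
        raise ValueError("need at least 3 segments")
    zc = zz - zz.mean(axis=0)
    xc = X - X.mean(axis=0)
    zs = zz.std(axis=0)
    xs = X.std(axis=0)
    x_const = xs <= 1e-12
    z_const = zs <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (zc.T @ xc) / zz.shape[0] / np.outer(zs, xs)
    corr[:, x_const] = np.nan
    corr[z_const, :] = np.nan
    return corr


def cluster_segments(
    z,
    k: int = 2,
    strength: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratify segments into k types on the top-2 kernel PCs of z.

    Kernel PCA uses an RBF kernel with bandwidth set to the median
    pairwise embedding distance; k-means (fixed seed) clusters the two
    components. When per-segment interaction ``strength`` is given,
    labels are permuted so label 0 ("type 1") has the highest mean
    strength, making the typing reproducible across seeds. Returns
    (labels, components).
    """
    zz = z.z if isinstance(z, Embedding) else np.asarray(z, dtype=float)
    if len(zz) < k:
        raise ValueError("fewer segments than clusters")
    if np.allclose(zz, zz[0]):
        raise ValueError("degenerate identical embeddings")
    if k == 1:
        comps = KernelPCA(n_components=2, kernel="rbf").fit_transform(zz)
        return np.zeros(len(zz), dtype=int), comps
    diffs = zz[:, None, :] - zz[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))
    med = np.median(dists[np.triu_indices(len(zz), k=1)])
    gamma = 1.0 / (2.0 * med**2) if med > 0 else None
    comps = KernelPCA(n_components=2, kernel="rbf", gamma=gamma).fit_transform(zz)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(comps)
    labels = km.labels_
    if strength is not None:
        strength = np.asarray(strength, dtype=float)
        means = [strength[labels == c].mean() if np.any(labels == c) else -np.inf
                 for c in range(k)]
        order = np.argsort(-np.asarray(means))  # order[0] = strongest cluster
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]
    return labels, comps
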