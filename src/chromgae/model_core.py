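"""The graph autoencoder: edge convolution with distance-signed attention.

The encoder is three edge-convolution layers. Layer l updates node i as

    h_i^{l+1} = sigmoid( Σ_{j ∈ N(i)} a_ij^l · ( W^l·[h_j − h_i ‖ h_i] + b^l ) )

where a_ij = ω_ij · (1/H) Σ_k α_ij^k combines the signed distance weight
ω_ij = ln(d_ij / flip_range) with H = 8 heads of scaled dot-product
attention softmax-normalized over each target's neighborhood. Layer
output dimensions are 32, 16, 32; the 14 input features are zero-padded
to 16 so every layer input splits evenly into 8 heads. The decoder is a
plain inner product of the 32-dimensional embeddings, and training
minimizes the MSE against the segment-pair interaction scores.

Messages flow in both directions of every undirected edge with the same
ω. A node with no neighbors aggregates the zero vector and therefore
embeds as sigmoid(0) = 0.5 in every coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    RowGrouper,
    Tensor,
    concat,
    constant,
    parameter,
    segment_softmax,
)
from .graph_dataset import SegmentGraph

__all__ = [
    "LayerParams",
    "EncoderParams",
    "Embedding",
    "Adam",
    "edge_message",
    "attention_coefficients",
    "encode",
    "encode_features",
    "decode",
    "mse_loss",
    "forward_loss",
    "save_params",
    "load_params",
]

LAYER_DIMS = (32, 16, 32)
N_HEADS = 8
INPUT_DIM = 14
PADDED_DIM = 16  # 14 features zero-padded so 8 heads divide the input


@dataclass
class LayerParams:
    """Trainable arrays of one edge-convolution layer.

    ``W`` maps the concatenated pair representation (2·d_in → d_out),
    ``Q``/``K`` are the stacked per-head query/key projections
    (d_in → d_in, H heads of width d_in / H).
    """

    W: Tensor
    b: Tensor
    Q: Tensor
    K: Tensor

    @property
    def d_in(self) -> int:
        return self.W.shape[0] // 2

    @property
    def d_out(self) -> int:
        return self.W.shape[1]

    def tensors(self) -> list[Tensor]:
        return [self.W, self.b, self.Q, self.K]


@dataclass
class EncoderParams:
    """Three edge-convolution layers (16→32, 32→16, 16→32) with 8 heads."""

    layers: list[LayerParams]
    heads: int = N_HEADS

    def __post_init__(self) -> None:
        if len(self.layers) != 3:
            raise ValueError("the encoder has exactly 3 layers")
        for lp in self.layers:
            if lp.d_in % self.heads:
                raise ValueError(
                    f"layer input dim {lp.d_in} not divisible by {self.heads} heads"
                )

    def tensors(self) -> list[Tensor]:
        return [t for lp in self.layers for t in lp.tensors()]

    @classmethod
    def init(cls, rng: np.random.Generator, heads: int = N_HEADS) -> "EncoderParams":
        dims_in = (PADDED_DIM,) + LAYER_DIMS[:-1]
        layers = []
        for d_in, d_out in zip(dims_in, LAYER_DIMS):
            # Glorot-uniform for W, scaled-normal for the projections
            lim = np.sqrt(6.0 / (2 * d_in + d_out))
            layers.append(
                LayerParams(
                    W=parameter(rng.uniform(-lim, lim, size=(2 * d_in, d_out))),
                    b=parameter(np.zeros(d_out)),
                    Q=parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, d_in))),
                    K=parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, d_in))),
                )
            )
        return cls(layers=layers, heads=heads)


@dataclass
class Embedding:
    """Final-layer node representations, one 32-vector per segment."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("embedding contains non-finite entries")


def _directed(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand undirected (i, j) pairs into both directions.

    Returns (src, tgt, undirected_index) so per-edge quantities (ω) can
    be broadcast to both directions.
    """
    e = np.asarray(edges)
    src = np.concatenate([e[:, 1], e[:, 0]])
    tgt = np.concatenate([e[:, 0], e[:, 1]])
    orig = np.concatenate([np.arange(len(e)), np.arange(len(e))])
    return src, tgt, orig


def edge_message(h_i: np.ndarray, h_j: np.ndarray, layer: LayerParams) -> np.ndarray:
    """Single-pair message W·[h_j − h_i ‖ h_i] + b (i = target)."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape[-1] != layer.d_in or h_j.shape[-1] != layer.d_in:
        raise ValueError(
            f"expected vectors of dim {layer.d_in}, got {h_i.shape[-1]}"
        )
    pair = np.concatenate([h_j - h_i, h_i], axis=-1)
    return pair @ layer.W.data + layer.b.data


def _messages(h: Tensor, src, tgt, layer: LayerParams,
              g_src=None, g_tgt=None) -> Tensor:
    hs = h.gather(src, g_src)
    ht = h.gather(tgt, g_tgt)
    return concat([hs - ht, ht], axis=1) @ layer.W + layer.b


def _attention(
    h: Tensor,
    src: np.ndarray,
    tgt: np.ndarray,
    omega: np.ndarray,
    layer: LayerParams,
    heads: int,
    g_src: RowGrouper | None = None,
    g_tgt: RowGrouper | None = None,
) -> Tensor:
    """a_ij = ω_ij · mean over heads of softmax-normalized attention."""
    n, d_in = h.shape
    d_head = d_in // heads
    q = (h @ layer.Q).gather(tgt, g_tgt).reshape(-1, heads, d_head)
    k = (h @ layer.K).gather(src, g_src).reshape(-1, heads, d_head)
    logits = (q * k).sum(axis=2) * (1.0 / np.sqrt(d_head))  # (E, heads)
    alpha = segment_softmax(logits, tgt, n, g_tgt)
    mean_alpha = alpha.sum(axis=1) * (1.0 / heads)  # (E,)
    return mean_alpha * constant(omega)


def attention_coefficients(
    h: np.ndarray,
    edges: np.ndarray,
    omega: np.ndarray,
    layer: LayerParams,
    heads: int = N_HEADS,
) -> dict[tuple[int, int], float]:
    """Evaluate a_ij for every directed edge (target i ← source j)."""
    src, tgt, orig = _directed(edges)
    a = _attention(
        constant(np.asarray(h, dtype=float)),
        src,
        tgt,
        np.asarray(omega)[orig],
        layer,
        heads,
    )
    return {(int(i), int(j)): float(v) for i, j, v in zip(tgt, src, a.data)}


def encode_features(
    X: Tensor, edges: np.ndarray, edge_weight: np.ndarray, params: EncoderParams
) -> Tensor:
    """Differentiable encoder over an explicit feature Tensor.

    Accepts the raw 14-dim features (padded internally), the undirected
    edge list, and the per-edge signed weights; used both by the plain
    forward pass and by the explainer, whose gradient flows into X.
    """
    n, d = X.shape
    if d != INPUT_DIM:
        raise ValueError(f"expected {INPUT_DIM}-dim node features, got {d}")
    h = concat([X, constant(np.zeros((n, PADDED_DIM - d)))], axis=1)
    src, tgt, orig = _directed(edges)
    omega = np.asarray(edge_weight)[orig] if len(edges) else np.zeros(0)
    g_src = RowGrouper(src, n) if len(src) else None
    g_tgt = RowGrouper(tgt, n) if len(src) else None
    for li, layer in enumerate(params.layers):
        if len(src):
            a = _attention(h, src, tgt, omega, layer, params.heads, g_src, g_tgt)
            m = _messages(h, src, tgt, layer, g_src, g_tgt)
            agg = (m * a.reshape(-1, 1)).scatter_add(tgt, n, g_tgt)
        else:
            agg = constant(np.zeros((n, layer.d_out)))
        h = agg.sigmoid()
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError(f"non-finite activations in layer {li}")
    return h


def _encode_graph(graph: SegmentGraph, params: EncoderParams) -> Tensor:
    X = constant(np.asarray(graph.node_features, dtype=float))
    return encode_features(X, graph.edges, graph.edge_weight, params)


def encode(graph: SegmentGraph, params: EncoderParams) -> Embedding:
    """Run the 3-layer encoder; returns the n × 32 embedding."""
    return Embedding(z=_encode_graph(graph, params).data)


def decode(z, pairs) -> np.ndarray:
    """Inner-product decoder: score(i, j) = z_i · z_j (symmetric)."""
    zz = z.z if isinstance(z, Embedding) else np.asarray(z, dtype=float)
    pairs = np.asarray(pairs)
    if len(pairs) == 0:
        return np.zeros(0)
    return np.einsum("ed,ed->e", zz[pairs[:, 0]], zz[pairs[:, 1]])


def mse_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean squared error over labeled edges."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if pred.shape != label.shape:
        raise ValueError("pred and label must have equal length")
    if pred.size == 0:
        raise ValueError("empty label set")
    return float(np.mean((pred - label) ** 2))


def loss_and_pred(
    graph: SegmentGraph, params: EncoderParams
) -> tuple[Tensor, np.ndarray]:
    """Differentiable MSE against the graph's labels, plus the predictions."""
    if graph.edge_label is None or len(graph.edge_label) == 0:
        raise ValueError("graph has no edge labels to fit")
    z = _encode_graph(graph, params)
    zi = z.gather(graph.edges[:, 0])
    zj = z.gather(graph.edges[:, 1])
    pred = (zi * zj).sum(axis=1)
    loss = (pred - constant(graph.edge_label)).square().mean()
    return loss, pred.data


def forward_loss(graph: SegmentGraph, params: EncoderParams) -> Tensor:
    """Differentiable MSE of decoded scores against the graph's labels."""
    return loss_and_pred(graph, params)[0]


class Adam:
    """Adam with decoupled weight decay over a list of parameter tensors.

    ``weight_decay`` shrinks parameters directly (AdamW style), which
    among other things lets training forget weights on uninformative
    inputs; set it to 0 for plain Adam.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps)
                + self.weight_decay * p.data
            )


def save_params(path, params: EncoderParams, meta: dict | None = None) -> None:
    """Checkpoint as a JSON archive of named arrays plus a manifest."""
    payload = {
        "manifest": {
            "schema_version": 1,
            "layer_dims": list(LAYER_DIMS),
            "heads": params.heads,
            **(meta or {}),
        },
        "arrays": {
            f"layer{li}.{name}": getattr(lp, name).data.tolist()
            for li, lp in enumerate(params.layers)
            for name in ("W", "b", "Q", "K")
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_params(path) -> EncoderParams:
    with open(path) as fh:
        payload = json.load(fh)
    arrays = payload["arrays"]
    layers = [
        LayerParams(
            **{
                name: parameter(np.array(arrays[f"layer{li}.{name}"]))
                for name in ("W", "b", "Q", "K")
            }
        )
        for li in range(3)
    ]
    return EncoderParams(layers=layers, heads=payload["manifest"]["heads"])
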