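"""GCN backbone: stacked graph convolutions, global average pooling, softmax.

Layer rule: ``F(l) = sigma( D^{-1/2} (A+I) D^{-1/2} F(l-1) W(l) )`` with
``F(0) = X``; the pooled node-mean of the last layer feeds a single affine
head and a softmax.  All forward math runs through the autodiff engine so
saliency maps (gradients of class scores) remain differentiable in the
weights, which is what explanation supervision trains against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import AtlasGraph, GraphDataset

ACTIVATIONS = ("relu", "linear")


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization with self-loops (numpy in/out)."""
    return normalize_adjacency_t(ad.tensor(np.asarray(a, dtype=float))).data


def normalize_adjacency_t(a: Tensor) -> Tensor:
    """Tensor version of :func:`normalize_adjacency`; supports batches."""
    n = a.shape[-1]
    eye = np.eye(n)
    at = a + ad.tensor(eye)  # self-loops guarantee degree >= 1
    deg = at.sum(axis=-1)
    dinv = deg**-0.5
    col = dinv.reshape(dinv.shape + (1,))
    row = dinv.reshape(dinv.shape[:-1] + (1, dinv.shape[-1]))
    return at * col * row


@dataclass
class BackboneParams:
    """Trainable weights of the GCN classifier."""

    layer_weights: List[Tensor]
    head_weight: Tensor  # (d_L, C)
    head_bias: Tensor  # (C,)
    activation: str = "relu"
    hidden_dims: Sequence[int] = (16, 16, 16)

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not self.layer_weights:
            raise ValueError("need at least one conv layer")
        dims = [w.shape for w in self.layer_weights]
        for (a, b), (c, _) in zip(dims, dims[1:]):
            if b != c:
                raise ValueError("layer dimension chain inconsistent")
        if self.head_weight.shape[0] != dims[-1][1]:
            raise ValueError("head input dim must match last conv layer")

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)

    @property
    def n_classes(self) -> int:
        return self.head_weight.shape[1]

    @property
    def d_in(self) -> int:
        return self.layer_weights[0].shape[0]

    def trainable(self) -> List[Tensor]:
        return list(self.layer_weights) + [self.head_weight, self.head_bias]

    def copy(self) -> "BackboneParams":
        return BackboneParams(
            [Tensor(w.data.copy(), requires_grad=True) for w in self.layer_weights],
            Tensor(self.head_weight.data.copy(), requires_grad=True),
            Tensor(self.head_bias.data.copy(), requires_grad=True),
            self.activation,
            tuple(self.hidden_dims),
        )

    @classmethod
    def init(cls, d_in: int, n_classes: int, hidden_dims: Sequence[int] = (16, 16, 16),
             activation: str = "relu", seed: int = 0) -> "BackboneParams":
        """Glorot-uniform initialization, deterministic given ``seed``."""
        rng = np.random.default_rng(seed)
        dims = [d_in, *hidden_dims]
        weights = []
        for a, b in zip(dims, dims[1:]):
            lim = np.sqrt(6.0 / (a + b))
            weights.append(Tensor(rng.uniform(-lim, lim, size=(a, b)), requires_grad=True))
        lim = np.sqrt(6.0 / (dims[-1] + n_classes))
        head_w = Tensor(rng.uniform(-lim, lim, size=(dims[-1], n_classes)), requires_grad=True)
        head_b = Tensor(np.zeros(n_classes), requires_grad=True)
        return cls(weights, head_w, head_b, activation, tuple(hidden_dims))


@dataclass
class ForwardTrace:
    """Per-sample record of a forward pass (numpy views of the tensors)."""

    activations: List[np.ndarray]  # F(0)..F(L), each (N, d_l)
    pooled: np.ndarray  # (d_L,)
    logits: np.ndarray  # (C,)
    probabilities: np.ndarray  # (C,)


def forward_tensors(a: Tensor, x: Tensor, params: BackboneParams,
                    activation: Optional[str] = None):
    """Forward pass on tensors; supports a leading batch axis.

    Returns ``(activations, pooled, logits)`` where ``activations`` is the
    list ``[F(0), ..., F(L)]`` of tensors (retained for the explainers).
    ``activation`` may override the stored nonlinearity — ``"guided"``
    swaps in the guided-backprop rectifier (identical forward values).
    """
    act = activation or params.activation
    ahat = normalize_adjacency_t(a)
    f = x
    acts = [f]
    for w in params.layer_weights:
        z = ahat @ f @ w
        if act == "relu":
            f = z.relu()
        elif act == "guided":
            f = z.guided_relu()
        else:  # linear
            f = z
        acts.append(f)
    pooled = f.mean(axis=-2)
    logits = pooled @ params.head_weight + params.head_bias
    return acts, pooled, logits


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gcn_forward(graph: AtlasGraph, params: BackboneParams) -> ForwardTrace:
    """Single-sample forward pass returning all layer activations."""
    if graph.features.shape[1] != params.d_in:
        raise ValueError("feature dimension does not match backbone input dim")
    acts, pooled, logits = forward_tensors(
        ad.tensor(graph.adjacency), ad.tensor(graph.features), params)
    probs = softmax(logits.data)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):  # pragma: no cover
        raise FloatingPointError("probabilities failed to normalize")
    return ForwardTrace([f.data for f in acts], pooled.data, logits.data, probs)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of batched logits ``(Z, C)`` against int labels."""
    z = logits.shape[0]
    m = ad.tensor(np.max(logits.data, axis=-1, keepdims=True))  # stability shift
    lse = ((logits - m).exp().sum(axis=-1)).log() + m.reshape((z,))
    picked = logits[(np.arange(z), labels)]
    return (lse - picked).mean()


def cross_entropy_per_sample(logits: Tensor, labels: np.ndarray) -> Tensor:
    z = logits.shape[0]
    m = ad.tensor(np.max(logits.data, axis=-1, keepdims=True))
    lse = ((logits - m).exp().sum(axis=-1)).log() + m.reshape((z,))
    return lse - logits[(np.arange(z), labels)]


@dataclass
class BaselineHistory:
    loss: list = field(default_factory=list)

    @property
    def final(self) -> float:
        return self.loss[-1]


def train_baseline(dataset: GraphDataset, epochs: int = 200, lr: float = 1e-3,
                   hidden_dims: Sequence[int] = (16, 16, 16), activation: str = "relu",
                   seed: int = 0, params: Optional[BackboneParams] = None):
    """Train the plain GCN classifier (prediction loss only), full batch.

    Returns ``(BackboneParams, BaselineHistory)``; deterministic given seed.
    """
    params = params.copy() if params is not None else BackboneParams.init(
        dataset.d_in, dataset.n_classes, hidden_dims, activation, seed)
    a = ad.tensor(dataset.adjacency_stack())
    x = ad.tensor(dataset.feature_stack())
    y = dataset.labels()
    opt = ad.Adam(params.trainable(), lr=lr)
    history = BaselineHistory()
    for _ in range(epochs):
        _, _, logits = forward_tensors(a, x, params)
        loss = cross_entropy(logits, y)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite training loss: {loss.item()}")
        grads = ad.grad(loss, params.trainable())
        opt.step(grads)
        history.loss.append(loss.item())
    return params, history


def predict_proba(params: BackboneParams, dataset: GraphDataset) -> np.ndarray:
    _, _, logits = forward_tensors(
        ad.tensor(dataset.adjacency_stack()), ad.tensor(dataset.feature_stack()), params)
    return softmax(logits.data)


def predict(params: BackboneParams, dataset: GraphDataset) -> np.ndarray:
    return predict_proba(params, dataset).argmax(axis=1)
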