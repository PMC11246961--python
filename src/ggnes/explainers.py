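"""Per-sample node and edge saliency, differentiable in the backbone weights.

Three gradient-flavoured methods are provided — plain gradients, guided
backpropagation and Grad-CAM.  Node scores are norms over feature channels
of the rectified gradient of the class score w.r.t. a layer's activations;
edge scores are rectified gradients of the class score w.r.t. the raw
adjacency entries, with the chain rule flowing through the symmetric degree
normalization.  Perturbation- and surrogate-style explainers are out of
scope by design: they need their own optimization loop and therefore cannot
be trained end-to-end under explanation supervision.

The class score ``y_c`` is the pre-softmax logit: softmax compresses
gradients toward zero on confident samples, which is the standard reason
saliency is taken on logits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BackboneParams, forward_tensors
from .data import AtlasGraph

METHODS = ("gradient", "guided_bp", "grad_cam")
NORMS = ("l2", "l1")


def default_layer(params: BackboneParams) -> int:
    """Deepest conv layer whose node gradients are not structurally uniform.

    Mean pooling followed by an affine head makes ``dy_c/dF(L)`` identical
    for every node, so last-layer gradient node saliency carries no spatial
    information; one layer below is the deepest informative choice.
    """
    return max(1, params.n_layers - 1)


@dataclass
class LocalExplanation:
    """Nonnegative per-sample node/edge importance for one class."""

    sample_id: str
    class_id: int
    layer_id: int
    method: str
    node_scores: Optional[np.ndarray] = None  # (N,)
    edge_scores: Optional[np.ndarray] = None  # (N, N) symmetric, zero diag

    def __post_init__(self):
        if self.node_scores is None and self.edge_scores is None:
            raise ValueError("at least one of node/edge scores required")
        if self.node_scores is not None and self.node_scores.min() < 0:
            raise ValueError("node scores must be nonnegative")
        if self.edge_scores is not None:
            e = self.edge_scores
            if e.min() < 0 or not np.array_equal(e, e.T):
                raise ValueError("edge scores must be nonnegative and symmetric")


def _feature_norm(g: Tensor, norm: str) -> Tensor:
    """|| ReLU(g) || over the trailing feature axis."""
    r = g.relu()
    if norm == "l2":
        s = (r * r).sum(axis=-1)
        # masked sqrt: exact 0 (with zero gradient) where the norm vanishes
        safe = (s + 1e-300) ** 0.5
        return ad.where(s.data > 0, safe, ad.tensor(np.zeros(s.shape)))
    return r.sum(axis=-1)  # l1 of a nonnegative tensor


def _symmetrize_zero_diag(s: Tensor) -> Tensor:
    n = s.shape[-1]
    sym = (s + _swap_last(s)) * 0.5
    return sym * ad.tensor(1.0 - np.eye(n))


def _swap_last(t: Tensor) -> Tensor:
    ax = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(ax)


def batch_saliency(params: BackboneParams, adjacency: np.ndarray, features: np.ndarray,
                   c: int, layer: Optional[int] = None, method: str = "gradient",
                   norm: str = "l2", need_node: bool = True, need_edge: bool = True,
                   create_graph: bool = False):
    """Node/edge saliency for a stack of samples ``(K, N, N)`` at once.

    Returns ``(node, edge)`` tensors of shapes ``(K, N)`` and ``(K, N, N)``
    (either may be None).  With ``create_graph=True`` the outputs remain
    differentiable w.r.t. the backbone weights — the property the
    supervision loss relies on.  Each sample's scores depend only on its own
    slice, so batching is exact.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if norm not in NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    layer = default_layer(params) if layer is None else layer
    if not 1 <= layer <= params.n_layers:
        raise ValueError(f"layer must be in 1..{params.n_layers}")
    if not 0 <= c < params.n_classes:
        raise ValueError("class id out of range")

    a = Tensor(np.asarray(adjacency, float), requires_grad=need_edge)
    x = ad.tensor(np.asarray(features, float))
    act_kind = "guided" if method == "guided_bp" else None
    acts, _, logits = forward_tensors(a, x, params, activation=act_kind)
    score = logits[(slice(None), c)].sum()  # sum of per-sample logits

    node = edge = None
    if method in ("gradient", "guided_bp"):
        wrt = []
        if need_node:
            wrt.append(acts[layer])
        if need_edge:
            wrt.append(a)
        gs = ad.grad(score, wrt, create_graph=create_graph)
        if need_node:
            node = _feature_norm(gs[0], norm)
        if need_edge:
            edge = _symmetrize_zero_diag(gs[-1].relu())
    else:  # grad_cam
        f_l = acts[layer]
        (g_f,) = ad.grad(score, [f_l], create_graph=create_graph)
        alpha = g_f.mean(axis=-2, keepdims=True)  # channel weights per sample
        cam = (alpha * f_l).sum(axis=-1).relu()  # (K, N)
        if need_node:
            node = cam
        if need_edge:
            # edge analogue: sensitivity of the total CAM mass to each
            # adjacency entry, channel weights held fixed
            alpha_fixed = alpha.detach()
            cam_fixed = (alpha_fixed * f_l).sum(axis=-1).relu()
            (g_a,) = ad.grad(cam_fixed.sum(), [a], create_graph=create_graph)
            edge = _symmetrize_zero_diag(g_a.relu())
    return node, edge


def local_node_explanation(params: BackboneParams, graph: AtlasGraph, c: int,
                           layer: Optional[int] = None, method: str = "gradient",
                           norm: str = "l2") -> LocalExplanation:
    """Node importance of one sample for class ``c`` at conv layer ``layer``
    (defaults to the last layer)."""
    node, _ = batch_saliency(params, graph.adjacency[None], graph.features[None],
                             c, layer, method, norm, need_node=True, need_edge=False)
    layer = default_layer(params) if layer is None else layer
    return LocalExplanation(graph.sample_id, c, layer, method,
                            node_scores=node.data[0])


def local_edge_explanation(params: BackboneParams, graph: AtlasGraph, c: int,
                           layer: Optional[int] = None, method: str = "gradient",
                           norm: str = "l2") -> LocalExplanation:
    """Edge importance of one sample for class ``c`` (symmetric, zero diag)."""
    _, edge = batch_saliency(params, graph.adjacency[None], graph.features[None],
                             c, layer, method, norm, need_node=False, need_edge=True)
    layer = default_layer(params) if layer is None else layer
    return LocalExplanation(graph.sample_id, c, layer, method,
                            edge_scores=edge.data[0])
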