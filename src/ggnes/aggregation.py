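"""Collapse per-sample local explanations into per-class global ones.

The simple aggregators are elementwise min / max / mean over the samples of
one class; the concept-based alternative lives in :mod:`ggnes.concepts`.
All three propagate gradients (min/max through the selected element), so a
supervision loss on the aggregate reaches the backbone weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .explainers import LocalExplanation

MODES = ("min", "max", "avg")

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class GlobalExplanation:
    """Per-class aggregated node vectors and edge matrices."""

    node: Dict[int, np.ndarray] = field(default_factory=dict)
    edge: Dict[int, np.ndarray] = field(default_factory=dict)
    mode: str = "avg"
    normalized: bool = False


def _reduce(stacked: ArrayLike, mode: str) -> ArrayLike:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if isinstance(stacked, Tensor):
        if mode == "min":
            return stacked.min(axis=0)
        if mode == "max":
            return stacked.max(axis=0)
        return stacked.mean(axis=0)
    return {"min": np.min, "max": np.max, "avg": np.mean}[mode](stacked, axis=0)


def _check_consistent(locals_: List[LocalExplanation], attr: str):
    if not locals_:
        raise ValueError("no samples for class")
    layers = {e.layer_id for e in locals_}
    classes = {e.class_id for e in locals_}
    if len(layers) > 1:
        raise ValueError("mixed layers in aggregation")
    if len(classes) > 1:
        raise ValueError("mixed classes in aggregation")
    if any(getattr(e, attr) is None for e in locals_):
        raise ValueError(f"{attr} missing from some local explanations")


def aggregate_node(locals_: List[LocalExplanation], mode: str = "avg") -> np.ndarray:
    """Elementwise min/max/mean of node scores over one class's samples."""
    _check_consistent(locals_, "node_scores")
    return _reduce(np.stack([e.node_scores for e in locals_]), mode)


def aggregate_edge(locals_: List[LocalExplanation], mode: str = "avg") -> np.ndarray:
    """Elementwise min/max/mean of edge score matrices (symmetry preserved)."""
    _check_consistent(locals_, "edge_scores")
    return _reduce(np.stack([e.edge_scores for e in locals_]), mode)


def aggregate_tensor(stacked: Tensor, mode: str = "avg") -> Tensor:
    """Aggregator on an already-stacked tensor (axis 0 = samples);
    used inside the training loop so gradients flow."""
    return _reduce(stacked, mode)


def normalize_explanation(raw: ArrayLike) -> ArrayLike:
    """Scale a nonnegative explanation into [0,1] by its max entry.

    All-zero input is returned unchanged.  For tensors the max is detached:
    gradients flow through the scores, not through the scale, keeping the
    supervision signal well-behaved.
    """
    if isinstance(raw, Tensor):
        if raw.data.min() < 0:
            raise ValueError("explanation must be nonnegative")
        mx = float(raw.data.max())
        return raw if mx == 0.0 else raw * (1.0 / mx)
    raw = np.asarray(raw, dtype=float)
    if raw.min(initial=0.0) < 0:
        raise ValueError("explanation must be nonnegative")
    mx = raw.max(initial=0.0)
    return raw if mx == 0.0 else raw / mx
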