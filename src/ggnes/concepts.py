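"""Concept-based global explainer: prototypes + logic formulas.

Local edge explanations are binarized into small subgraphs, embedded by a
permutation-invariant graph encoder, and clustered around ``m`` learnable
prototype vectors.  An interpretable linear "entropy" logic layer maps
soft prototype activations to class scores; thresholding its behaviour on
all 2^m Boolean prototype patterns yields one Boolean formula per class
(e.g. ``class1 ⇔ P0 ∨ (P1 ∧ P2)``).  Projecting a class formula back onto
the atlas — prototype-wise membership-weighted node indicators combined by
max (∨) and min (∧) — produces the per-class global node explanation used
for supervision.

Distances between embeddings and prototypes are Euclidean, with
``softmax(-d)`` soft assignments; ties in hard assignment go to the lowest
prototype index.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import sympy
from sympy.logic import SOPform

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import normalize_adjacency_t
from .explainers import LocalExplanation


# -- explanation subgraphs ----------------------------------------------------


@dataclass(frozen=True)
class ExplanationSubgraph:
    """A binarized local explanation: the kept edges and their endpoints."""

    kept_edges: tuple  # ((i, j), ...) with i < j
    kept_nodes: tuple
    sample_id: str
    label: int  # source class (ground truth of the sample)
    n_nodes: int
    edge_weights: tuple = ()  # scores aligned with kept_edges
    degenerate: bool = False

    def adjacency(self, weighted: bool = True) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in zip(self.kept_edges, self.edge_weights or
                             [1.0] * len(self.kept_edges)):
            a[i, j] = a[j, i] = w if weighted else 1.0
        mx = a.max(initial=0.0)
        return a / mx if (weighted and mx > 0) else a

    def node_indicator(self) -> np.ndarray:
        v = np.zeros(self.n_nodes)
        v[list(self.kept_nodes)] = 1.0
        return v


def binarize_explanation(local: LocalExplanation, top_fraction: float = 0.25) -> ExplanationSubgraph:
    """Keep the ``ceil(top_fraction * nnz)`` highest-scoring edges.

    Ties at the cut are broken by lexicographic node-pair order.  All-zero
    score maps yield a subgraph flagged degenerate (excluded from
    clustering downstream).
    """
    if local.edge_scores is None:
        raise ValueError("binarization needs edge scores")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    e = local.edge_scores
    n = e.shape[0]
    entries = [(-e[i, j], i, j) for i in range(n) for j in range(i + 1, n) if e[i, j] > 0]
    if not entries:
        return ExplanationSubgraph((), (), local.sample_id, local.class_id, n,
                                   degenerate=True)
    entries.sort()
    k = int(np.ceil(top_fraction * len(entries)))
    kept = entries[:k]
    edges = tuple((i, j) for _, i, j in kept)
    weights = tuple(float(-s) for s, _, _ in kept)
    nodes = tuple(sorted({v for ij in edges for v in ij}))
    return ExplanationSubgraph(edges, nodes, local.sample_id, local.class_id, n,
                               edge_weights=weights)


# -- Boolean formulas ---------------------------------------------------------


_OR, _AND, _NOT = "∨", "∧", "¬"


class Formula:
    """A Boolean combination of prototype literals P0..P(m-1)."""

    def __init__(self, expr, m: int):
        self.expr = sympy.simplify_logic(expr, form="dnf") if expr not in (
            sympy.true, sympy.false) else expr
        self.m = m

    @property
    def symbols(self):
        return sympy.symbols(f"P0:{self.m}")

    @classmethod
    def from_string(cls, s: str, m: int) -> "Formula":
        txt = (s.replace(_OR, "|").replace(_AND, "&").replace(_NOT, "~")
               .replace("⇔", "").strip())
        if "|" not in txt and "&" not in txt and txt.lower() in ("true", "false"):
            return cls(sympy.true if txt.lower() == "true" else sympy.false, m)
        local = {f"P{i}": sympy.Symbol(f"P{i}") for i in range(m)}
        return cls(sympy.sympify(txt, locals=local), m)

    def evaluate(self, bits: Sequence[int]) -> bool:
        sub = {sympy.Symbol(f"P{i}"): bool(b) for i, b in enumerate(bits)}
        return bool(self.expr.subs(sub))

    def __str__(self) -> str:
        return _print_expr(self.expr)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Formula({self!s})"


def _print_expr(e) -> str:
    if e is sympy.true:
        return "True"
    if e is sympy.false:
        return "False"
    if e.is_Symbol:
        return str(e)
    if isinstance(e, sympy.Not):
        return f"{_NOT}{_print_expr(e.args[0])}"
    if isinstance(e, sympy.And):
        parts = [_wrap(a) for a in e.args]
        return f" {_AND} ".join(sorted(parts))
    if isinstance(e, sympy.Or):
        parts = [_wrap(a) for a in e.args]
        return f" {_OR} ".join(sorted(parts))
    raise ValueError(f"unsupported expression node {e!r}")


def _wrap(a) -> str:
    s = _print_expr(a)
    return f"({s})" if isinstance(a, (sympy.And, sympy.Or)) else s


# -- concept model ------------------------------------------------------------


@dataclass
class GLGConfig:
    """Hyperparameters of the concept explainer fit."""

    epochs: int = 600
    lr: float = 0.01
    top_fraction: float = 0.25
    q: int = 8  # embedding dimension
    hidden: int = 16
    lambda_pull: float = 0.5  # embeddings toward nearest prototype
    lambda_cover: float = 0.5  # each prototype toward nearest embedding
    lambda_ent: float = 0.1  # confidence (low entropy) of assignments
    lambda_l1: float = 0.01  # sparsity of logic-layer weights
    seed: int = 0


@dataclass
class ConceptAssignment:
    membership: np.ndarray  # (S, m), rows on the simplex
    hard: np.ndarray  # (S,) cluster ids

    @classmethod
    def from_membership(cls, membership: np.ndarray) -> "ConceptAssignment":
        return cls(membership, membership.argmax(axis=1))


@dataclass
class ConceptModel:
    """Learned prototypes, subgraph encoder and per-class logic formulas."""

    m: int
    q: int
    n_classes: int
    n_nodes: int
    enc_w1: Tensor
    enc_w2: Tensor
    logic_w: Tensor  # (m, C)
    logic_b: Tensor  # (C,)
    prototypes: Tensor  # (m, q)
    formulas: Dict[int, Formula] = field(default_factory=dict)
    top_fraction: float = 0.25

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need m >= 2 prototypes")

    # encoding ---------------------------------------------------------------
    def encode_tensors(self, adj: Tensor, node_mask: np.ndarray) -> Tensor:
        """Embed a batch of subgraphs given (S,N,N) adjacency tensor and a
        binary (S,N) kept-node mask; mean-pools over kept nodes."""
        s = adj.shape[0]
        x = ad.tensor(np.broadcast_to(np.eye(self.n_nodes), (s, self.n_nodes, self.n_nodes)).copy())
        ahat = normalize_adjacency_t(adj)
        f1 = (ahat @ x @ self.enc_w1).relu()
        f2 = ahat @ f1 @ self.enc_w2  # linear output layer
        mask = ad.tensor(node_mask[:, :, None])
        counts = np.maximum(node_mask.sum(axis=1, keepdims=True), 1.0)
        return (f2 * mask).sum(axis=1) * ad.tensor(1.0 / counts)

    def embed_subgraphs(self, subgraphs: List[ExplanationSubgraph]) -> np.ndarray:
        if not subgraphs:
            raise ValueError("no subgraphs to embed")
        adj = ad.tensor(np.stack([g.adjacency() for g in subgraphs]))
        mask = np.stack([g.node_indicator() for g in subgraphs])
        return self.encode_tensors(adj, mask).data

    # activations ------------------------------------------------------------
    def activation_tensors(self, emb: Tensor) -> Tensor:
        """softmax(-distance) memberships, (S, m)."""
        diff = emb.reshape((emb.shape[0], 1, self.q)) - self.prototypes.reshape((1, self.m, self.q))
        d = ((diff * diff).sum(axis=-1) + 1e-12) ** 0.5
        neg = -d
        shift = ad.tensor(np.max(neg.data, axis=-1, keepdims=True))
        e = (neg - shift).exp()
        return e * (e.sum(axis=-1, keepdims=True) ** -1.0)

    def assign(self, subgraphs: List[ExplanationSubgraph]) -> ConceptAssignment:
        emb = ad.tensor(self.embed_subgraphs(subgraphs))
        return ConceptAssignment.from_membership(self.activation_tensors(emb).data)

    # logic layer ------------------------------------------------------------
    def logic_logits(self, activ: Tensor) -> Tensor:
        return activ @ self.logic_w + self.logic_b

    def predict_from_bits(self, bits: np.ndarray) -> np.ndarray:
        """Class predicted by the logic layer for Boolean prototype patterns
        ``bits`` of shape (S, m); ties go to the lower class index."""
        logits = self.logic_logits(ad.tensor(np.asarray(bits, float))).data
        return logits.argmax(axis=1)

    def formula_predictions(self, assignment: ConceptAssignment) -> np.ndarray:
        bits = np.eye(self.m)[assignment.hard]
        return self.predict_from_bits(bits)


def concept_activation(embedding: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Standalone softmax(-Euclidean distance) membership for one embedding."""
    d = np.sqrt(((embedding[None, :] - prototypes) ** 2).sum(axis=1))
    e = np.exp(-(d - d.min()))
    return e / e.sum()


def representative_element(prototype_id: int, subgraphs: List[ExplanationSubgraph],
                           model: ConceptModel) -> ExplanationSubgraph:
    """The subgraph whose embedding is closest to prototype ``prototype_id``
    (ties resolved by sample order)."""
    if not subgraphs:
        raise ValueError("empty subgraph collection")
    emb = model.embed_subgraphs(subgraphs)
    d = np.sqrt(((emb - model.prototypes.data[prototype_id][None, :]) ** 2).sum(axis=1))
    return subgraphs[int(np.argmin(d))]


# -- metrics ------------------------------------------------------------------


def concept_purity(assignment: ConceptAssignment, labels: Sequence[int]):
    """Mean and sd over nonempty clusters of the most-frequent-label share."""
    labels = np.asarray(labels)
    purities = []
    for j in range(assignment.membership.shape[1]):
        members = labels[assignment.hard == j]
        if members.size == 0:
            continue
        _, counts = np.unique(members, return_counts=True)
        purities.append(counts.max() / members.size)
    if not purities:
        raise ValueError("all clusters empty")
    return float(np.mean(purities)), float(np.std(purities))


def fidelity(formula_predictions: Sequence[int], gnn_predictions: Sequence[int]) -> float:
    """Agreement rate between logic-layer classes and backbone classes."""
    a, b = np.asarray(formula_predictions), np.asarray(gnn_predictions)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float((a == b).mean())


def formula_accuracy(formula_predictions: Sequence[int], true_labels: Sequence[int]) -> float:
    """Agreement rate between logic-layer classes and ground-truth labels."""
    return fidelity(formula_predictions, true_labels)


# -- formula extraction -------------------------------------------------------


def extract_formulas(model: ConceptModel,
                     observed_bits: Optional[np.ndarray] = None) -> Dict[int, Formula]:
    """Read one Boolean formula per class off the trained logic layer.

    Every one of the 2^m prototype on/off patterns is pushed through the
    logic layer; the minterms claimed by a class are simplified into
    disjunctive normal form.  Exact for the small m used here.

    ``observed_bits`` (the binarized prototype activations seen in
    training) marks never-observed patterns as don't-cares, so the
    minimizer describes the layer's behaviour on its actual input support;
    node masks encode presence, so if minimization still returns a formula
    without a positive literal the plain DNF of the observed minterms is
    kept instead.
    """
    syms = sympy.symbols(f"P0:{model.m}")
    patterns = list(itertools.product([0, 1], repeat=model.m))
    preds = model.predict_from_bits(np.array(patterns, float))
    observed = None
    if observed_bits is not None:
        observed = {tuple(int(b) for b in row) for row in np.asarray(observed_bits)}
    out = {}
    for c in range(model.n_classes):
        minterms = [list(p) for p, cls in zip(patterns, preds)
                    if cls == c and (observed is None or tuple(p) in observed)]
        if not minterms:
            expr = sympy.false
        else:
            dontcares = ([list(p) for p in patterns if tuple(p) not in observed]
                         if observed is not None else [])
            if len(minterms) + len(dontcares) == len(patterns):
                expr = sympy.true
            else:
                expr = SOPform(syms, minterms, dontcares)
            if expr not in (sympy.true, sympy.false) and not _has_positive_literal(expr):
                expr = sympy.Or(*[sympy.And(*[s if b else sympy.Not(s)
                                              for s, b in zip(syms, p)])
                                  for p in minterms])
        out[c] = Formula(expr, model.m)
    return out


def _has_positive_literal(expr) -> bool:
    if expr.is_Symbol:
        return True
    if isinstance(expr, sympy.Not):
        return False
    return any(_has_positive_literal(a) for a in expr.args)


# -- projection back to node space -------------------------------------------


def _prototype_node_vectors(memberships, node_ind: np.ndarray, hard: np.ndarray, m: int):
    """Per-prototype membership-weighted mean node indicator.

    ``memberships`` may be a Tensor (training path, gradients flow through
    the weights) or ndarray.  Clusters with no hard member fall back to a
    soft weighting over all subgraphs.
    """
    is_t = isinstance(memberships, Tensor)
    ind = ad.tensor(node_ind) if is_t else node_ind
    vecs = []
    for j in range(m):
        sel = (hard == j).astype(float)
        if sel.sum() == 0:
            sel = np.ones_like(sel)
        if is_t:
            w = memberships[(slice(None), j)] * ad.tensor(sel)
            num = (w.reshape((w.shape[0], 1)) * ind).sum(axis=0)
            den = w.sum() + 1e-12
            vecs.append(num * (den**-1.0))
        else:
            w = memberships[:, j] * sel
            vecs.append((w[:, None] * node_ind).sum(axis=0) / (w.sum() + 1e-12))
    return vecs


def _project_formula(expr, vecs, n: int, is_t: bool):
    zeros = ad.tensor(np.zeros(n)) if is_t else np.zeros(n)
    if expr is sympy.false:
        return None
    if expr is sympy.true:
        out = vecs[0]
        for v in vecs[1:]:
            out = ad.maximum(out, v) if is_t else np.maximum(out, v)
        return out
    if expr.is_Symbol:
        return vecs[int(str(expr)[1:])]
    if isinstance(expr, sympy.Not):
        return None  # node masks encode presence; negated literals carry no mass
    parts = [_project_formula(a, vecs, n, is_t) for a in expr.args]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    out = parts[0]
    combine = (ad.maximum if is_t else np.maximum) if isinstance(expr, sympy.Or) \
        else (ad.minimum if is_t else np.minimum)
    for p in parts[1:]:
        out = combine(out, p)
    return out


def project_node_explanation(model: ConceptModel, c: int, memberships,
                             node_ind: np.ndarray, hard: np.ndarray):
    """Class-c global node explanation from the formula and cluster contents.

    ∨ combines prototype node vectors by elementwise max, ∧ by min; the
    result is max-normalized to [0,1].  Differentiable through the
    memberships when they are tensors.
    """
    from .aggregation import normalize_explanation

    formula = model.formulas[c]
    is_t = isinstance(memberships, Tensor)
    vecs = _prototype_node_vectors(memberships, node_ind, hard, model.m)
    out = _project_formula(formula.expr, vecs, model.n_nodes, is_t)
    if out is None:
        warnings.warn(f"formula for class {c} has no positive literal; zero explanation")
        out = ad.tensor(np.zeros(model.n_nodes)) if is_t else np.zeros(model.n_nodes)
    return normalize_explanation(out)


def concept_global_node_explanation(model: ConceptModel,
                                    subgraphs: List[ExplanationSubgraph],
                                    c: int) -> np.ndarray:
    """Public (numpy) projection of class ``c``'s formula onto the atlas."""
    assignment = model.assign(subgraphs)
    node_ind = np.stack([g.node_indicator() for g in subgraphs])
    return project_node_explanation(model, c, assignment.membership, node_ind,
                                    assignment.hard)


# -- fitting ------------------------------------------------------------------


def fit_glg(locals_: List[LocalExplanation], gnn_predictions: Sequence[int],
            m: int, config: Optional[GLGConfig] = None,
            n_classes: Optional[int] = None) -> ConceptModel:
    """Jointly train encoder, prototypes and logic layer on binarized locals.

    The loss combines cross-entropy of the logic layer against the
    backbone's predictions, prototype pull/cover terms anchoring prototypes
    to embedding clusters, an entropy penalty sharpening assignments, and
    an L1 penalty on the logic weights.  Deterministic given
    ``config.seed``.
    """
    config = config or GLGConfig()
    if m < 2:
        raise ValueError("need m >= 2 prototypes")
    if not locals_:
        raise ValueError("no local explanations supplied")
    gnn_predictions = np.asarray(gnn_predictions)
    if len(gnn_predictions) != len(locals_):
        raise ValueError("one prediction per local explanation required")
    n_classes = n_classes or int(gnn_predictions.max()) + 1

    subs, preds = [], []
    for loc, p in zip(locals_, gnn_predictions):
        g = binarize_explanation(loc, config.top_fraction)
        if not g.degenerate:
            subs.append(g)
            preds.append(int(p))
    if not subs:
        raise ValueError("all local explanations binarized to empty subgraphs")
    preds = np.array(preds)
    n = subs[0].n_nodes
    distinct = {g.kept_edges for g in subs}
    if m > len(distinct):
        warnings.warn(f"m={m} exceeds the {len(distinct)} distinct subgraph structures")

    rng = np.random.default_rng(config.seed)
    dims = [(n, config.hidden), (config.hidden, config.q)]
    enc_w1, enc_w2 = (Tensor(rng.uniform(-np.sqrt(6 / sum(d)), np.sqrt(6 / sum(d)), d),
                             requires_grad=True) for d in dims)
    prototypes = Tensor(rng.uniform(0, 1, (m, config.q)), requires_grad=True)
    logic_w = Tensor(rng.uniform(-0.5, 0.5, (m, n_classes)), requires_grad=True)
    logic_b = Tensor(np.zeros(n_classes), requires_grad=True)

    model = ConceptModel(m, config.q, n_classes, n, enc_w1, enc_w2,
                         logic_w, logic_b, prototypes,
                         top_fraction=config.top_fraction)

    adj = ad.tensor(np.stack([g.adjacency() for g in subs]))
    mask = np.stack([g.node_indicator() for g in subs])
    params = [enc_w1, enc_w2, prototypes, logic_w, logic_b]
    opt = ad.Adam(params, lr=config.lr)
    from .backbone import cross_entropy

    for _ in range(config.epochs):
        emb = model.encode_tensors(adj, mask)
        diff = emb.reshape((emb.shape[0], 1, config.q)) - prototypes.reshape((1, m, config.q))
        d2 = (diff * diff).sum(axis=-1)  # (S, m)
        memb = model.activation_tensors(emb)
        ce = cross_entropy(model.logic_logits(memb), preds)
        pull = d2.min(axis=1).mean()
        cover = d2.min(axis=0).mean()
        ent = -(memb * (memb + 1e-12).log()).sum(axis=1).mean()
        l1 = logic_w.abs().mean()
        loss = (ce + config.lambda_pull * pull + config.lambda_cover * cover
                + config.lambda_ent * ent + config.lambda_l1 * l1)
        if not np.isfinite(loss.item()):
            raise FloatingPointError("non-finite concept-explainer loss")
        opt.step(ad.grad(loss, params))

    emb = model.encode_tensors(adj, mask)
    bits = (model.activation_tensors(emb).data >= 0.5).astype(int)
    model.formulas = extract_formulas(model, observed_bits=bits)
    return model
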