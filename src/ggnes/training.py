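"""The joint objective and iterative training loop for global explanation
supervision.

Objective (summed over classes c):

    L_Pred,c  +  alpha_n * dist(M_c, M'_c) + alpha_e * dist(E_c, E'_c)
              +  beta * consistency(M_c, E_c)  +  gamma * sparsity(M_c, E_c)

where M_c / E_c are the model's global node / edge explanations of class c
(min, max, avg aggregation of local saliency, or the concept projection),
M'_c / E'_c the per-class human masks.  The explanation loss applies only
to annotated classes; the two graph regularizers apply to every class.

Training is full batch: the cohorts this targets are tens to hundreds of
samples on atlases of tens of nodes, so the per-class aggregates are exact
at every step and runs are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .aggregation import GlobalExplanation, aggregate_tensor, normalize_explanation
from .backbone import (BackboneParams, cross_entropy_per_sample, forward_tensors,
                       predict, train_baseline)
from .concepts import (ConceptModel, GLGConfig, binarize_explanation, fit_glg,
                       project_node_explanation)
from .data import ClassExplanationLabel, GraphDataset
from .explainers import batch_saliency

ArrayLike = Union[np.ndarray, Tensor]

GLOBAL_MODES = ("min", "max", "avg", "concept")
DIST_KINDS = ("absolute", "squared")


@dataclass
class LossWeights:
    """Scale factors of the joint objective."""

    alpha_n: float = 1.0  # node explanation loss
    alpha_e: float = 0.1  # edge explanation loss; smaller than alpha_n so the
    # (sparse-target) edge term cannot overpower the prediction loss and
    # deaden the network's input sensitivity
    beta: float = 0.1  # node-edge consistency
    gamma: float = 0.01  # sparsity
    dist_kind: str = "absolute"

    def __post_init__(self):
        if min(self.alpha_n, self.alpha_e, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.dist_kind not in DIST_KINDS:
            raise ValueError(f"dist_kind must be one of {DIST_KINDS}")


# -- loss pieces --------------------------------------------------------------


def explanation_distance(a: ArrayLike, b: ArrayLike, kind: str = "absolute"):
    """Mean elementwise |a-b| or (a-b)^2."""
    if kind not in DIST_KINDS:
        raise ValueError(f"kind must be one of {DIST_KINDS}")
    at, bt = isinstance(a, Tensor), isinstance(b, Tensor)
    if not (at or bt):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.shape != b.shape:
            raise ValueError("shape mismatch")
        d = np.abs(a - b) if kind == "absolute" else (a - b) ** 2
        return float(d.mean())
    a, b = ad.tensor(a), ad.tensor(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    diff = a - b
    return (diff.abs() if kind == "absolute" else diff * diff).mean()


def explanation_loss(globals_: GlobalExplanation, labels: ClassExplanationLabel,
                     w: LossWeights):
    """Sum over annotated classes of the node + edge distance terms.

    A class annotated only at node (edge) level contributes no edge (node)
    term; with no annotated class at all the loss is 0 (with a warning).
    """
    import warnings

    total = 0.0
    seen = False
    for c in labels.annotated_classes:
        if c in labels.node_mask and c in globals_.node:
            total = total + w.alpha_n * explanation_distance(
                globals_.node[c], labels.node_mask[c], w.dist_kind)
            seen = True
        if c in labels.edge_mask and c in globals_.edge:
            total = total + w.alpha_e * explanation_distance(
                globals_.edge[c], labels.edge_mask[c], w.dist_kind)
            seen = True
    if not seen:
        warnings.warn("no annotated class: explanation loss is 0")
    return total


def consistency_regularizer(m_c: ArrayLike, e_c: ArrayLike, samples) -> ArrayLike:
    """Edge-importance-weighted smoothness of the node explanation.

    (1/T_c) sum_k (1/(2N^2)) sum_{i,j} E_{c,ij} A^k_{ij} (M_{c,i}-M_{c,j})^2
    over ordered pairs; zero when M_c is constant or E.A vanishes.
    ``samples`` is a list of AtlasGraph or an (T,N,N) array.
    """
    if hasattr(samples, "__len__") and len(samples) == 0:
        raise ValueError("empty class")
    if isinstance(samples, np.ndarray):
        abar = samples.mean(axis=0) if samples.ndim == 3 else samples
    else:
        abar = np.mean([g.adjacency for g in samples], axis=0)
    n = abar.shape[0]
    is_t = isinstance(m_c, Tensor) or isinstance(e_c, Tensor)
    if is_t:
        m_c, e_c = ad.tensor(m_c), ad.tensor(e_c)
        diff = m_c.reshape((n, 1)) - m_c.reshape((1, n))
        return (e_c * ad.tensor(abar) * diff * diff).sum() * (1.0 / (2 * n * n))
    m_c, e_c = np.asarray(m_c, float), np.asarray(e_c, float)
    diff = m_c[:, None] - m_c[None, :]
    return float((e_c * abar * diff**2).sum() / (2 * n * n))


def sparsity_regularizer(m_c: ArrayLike, e_c: ArrayLike) -> ArrayLike:
    """(1/N)||M_c||_1 + (1/N^2)||E_c||_1."""
    is_t = isinstance(m_c, Tensor) or isinstance(e_c, Tensor)
    if is_t:
        return ad.tensor(m_c).abs().mean() + ad.tensor(e_c).abs().mean()
    return float(np.abs(m_c).mean() + np.abs(e_c).mean())


# -- configuration / state ----------------------------------------------------


@dataclass
class TrainConfig:
    """Everything a supervised run needs; one seed drives all randomness."""

    mode: str = "avg"  # min | max | avg | concept
    local_method: str = "gradient"
    layer: Optional[int] = None  # None -> last conv layer
    norm: str = "l2"
    weights: LossWeights = field(default_factory=LossWeights)
    hidden_dims: tuple = (16, 16, 16)
    epochs: int = 200  # baseline (step-1) epochs
    supervised_epochs: Optional[int] = None  # defaults to 2*epochs: reshaping
    # saliency maps moves second-order quantities and needs more steps than
    # plain classification at the same learning rate
    lr: float = 1e-3
    seed: int = 0
    n_prototypes: int = 2
    glg: GLGConfig = field(default_factory=GLGConfig)
    max_outer_iters: int = 10
    proto_tol: float = 0.1  # relative: max prototype displacement between
    # outer iterations, as a fraction of the mean inter-prototype distance

    def __post_init__(self):
        if self.mode not in GLOBAL_MODES:
            raise ValueError(f"mode must be one of {GLOBAL_MODES}")
        if self.supervised_epochs is None:
            self.supervised_epochs = 2 * self.epochs


@dataclass
class TrainingState:
    backbone: BackboneParams
    config: TrainConfig
    concept: Optional[ConceptModel] = None
    history: List[dict] = field(default_factory=list)  # per-epoch components
    prototype_displacements: List[float] = field(default_factory=list)
    converged: bool = True
    n_outer_iters: int = 0

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


# -- objective ----------------------------------------------------------------


def _class_globals(params: BackboneParams, dataset: GraphDataset, cfg: TrainConfig,
                   need_node: bool, need_edge: bool, create_graph: bool = True):
    """Per-class normalized global node/edge explanation tensors from the
    training samples of each class."""
    node, edge = {}, {}
    for c in range(dataset.n_classes):
        idx = dataset.indices_of_class(c)
        a = dataset.adjacency_stack()[idx]
        x = dataset.feature_stack()[idx]
        nt, et = batch_saliency(params, a, x, c, cfg.layer, cfg.local_method,
                                cfg.norm, need_node=need_node, need_edge=need_edge,
                                create_graph=create_graph)
        if nt is not None:
            node[c] = normalize_explanation(aggregate_tensor(nt, cfg.mode))
        if et is not None:
            edge[c] = normalize_explanation(aggregate_tensor(et, cfg.mode))
    return node, edge


def total_objective(params: BackboneParams, dataset: GraphDataset,
                    labels: Optional[ClassExplanationLabel], cfg: TrainConfig,
                    concept_ctx: Optional[dict] = None):
    """Full objective on the (training) dataset.

    Returns ``(loss Tensor, components dict)``.  With all explanation
    weights zero this is exactly the mean cross-entropy.  ``concept_ctx``
    (concept mode) carries the fitted :class:`ConceptModel` and replaces
    each supervised class's M_c by the formula projection.
    """
    w = cfg.weights
    y = dataset.labels()
    a_t = ad.tensor(dataset.adjacency_stack())
    x_t = ad.tensor(dataset.feature_stack())
    _, _, logits = forward_tensors(a_t, x_t, params)
    ce = cross_entropy_per_sample(logits, y)
    loss = ce.mean()
    comp = {"L_pred": float(loss.item())}
    for c in range(dataset.n_classes):
        comp[f"L_pred_c{c}"] = float(ce.data[y == c].sum() / len(dataset))

    need_expl = (w.alpha_n > 0 or w.alpha_e > 0) and labels is not None \
        and bool(labels.annotated_classes)
    need_reg = w.beta > 0 or w.gamma > 0
    if not (need_expl or need_reg):
        return loss, comp

    mode_for_saliency = "avg" if cfg.mode == "concept" else cfg.mode
    node_g, edge_g = _class_globals(
        params, dataset, replace(cfg, mode=mode_for_saliency),
        need_node=True, need_edge=True)

    if cfg.mode == "concept" and concept_ctx is not None:
        node_g = dict(node_g)
        node_g.update(_concept_node_globals(params, dataset, cfg, concept_ctx))
        if "anchor_loss" in concept_ctx:
            loss = loss + concept_ctx.pop("anchor_loss")

    l_att_node = l_att_edge = 0.0
    if need_expl:
        for c in labels.annotated_classes:
            if w.alpha_n > 0 and c in labels.node_mask:
                term = explanation_distance(node_g[c], labels.node_mask[c], w.dist_kind)
                l_att_node = l_att_node + w.alpha_n * term
            if w.alpha_e > 0 and c in labels.edge_mask:
                term = explanation_distance(edge_g[c], labels.edge_mask[c], w.dist_kind)
                l_att_edge = l_att_edge + w.alpha_e * term
        for name, val in (("L_att_node", l_att_node), ("L_att_edge", l_att_edge)):
            comp[name] = float(val.item()) if isinstance(val, Tensor) else float(val)
        loss = loss + l_att_node + l_att_edge

    if need_reg:
        con = sp = 0.0
        adj = dataset.adjacency_stack()
        for c in range(dataset.n_classes):
            idx = dataset.indices_of_class(c)
            c_con = consistency_regularizer(node_g[c], edge_g[c], adj[idx])
            c_sp = sparsity_regularizer(node_g[c], edge_g[c])
            con = con + c_con
            sp = sp + c_sp
        comp["consistency"] = float(con.item()) if isinstance(con, Tensor) else float(con)
        comp["sparsity"] = float(sp.item()) if isinstance(sp, Tensor) else float(sp)
        loss = loss + w.beta * con + w.gamma * sp

    if not np.isfinite(loss.item()):
        raise FloatingPointError("non-finite objective component")
    comp["total"] = float(loss.item())
    return loss, comp


def _concept_node_globals(params: BackboneParams, dataset: GraphDataset,
                          cfg: TrainConfig, ctx: dict) -> Dict[int, Tensor]:
    """Concept-mode M_c: binarize fresh local edge saliency, embed with the
    frozen encoder, project the step-2 formula.

    The keep-masks are discrete (detached) but the encoder consumes the
    continuous edge scores on the kept support, so the result stays
    differentiable in the backbone weights; the prototypes receive gradient
    through the memberships.
    """
    model: ConceptModel = ctx["model"]
    a = dataset.adjacency_stack()
    x = dataset.feature_stack()
    preds = predict(params, dataset)
    out: Dict[int, Tensor] = {}
    # one saliency pass per predicted class, samples explained at their
    # predicted class like in the concept fit
    per_sample_edge: List[Optional[Tensor]] = [None] * len(dataset)
    for c in sorted(set(preds)):
        idx = np.nonzero(preds == c)[0]
        _, et = batch_saliency(params, a[idx], x[idx], int(c), cfg.layer,
                               cfg.local_method, cfg.norm,
                               need_node=False, need_edge=True, create_graph=True)
        for pos, i in enumerate(idx):
            per_sample_edge[i] = et[pos]

    keep_masks, node_inds, scales = [], [], []
    kept_rows = []
    for i, et in enumerate(per_sample_edge):
        e = et.data
        sub = binarize_explanation(
            _edge_only_local(e, f"i{i}", int(preds[i]), params.n_layers,
                             cfg.local_method), model.top_fraction)
        if sub.degenerate:
            continue
        mask = np.zeros_like(e)
        for (r, s) in sub.kept_edges:
            mask[r, s] = mask[s, r] = 1.0
        keep_masks.append(mask)
        node_inds.append(sub.node_indicator())
        scales.append(max(e[mask > 0].max(), 1e-12))
        kept_rows.append(i)
    if not kept_rows:
        return out
    masked = ad.stack([per_sample_edge[i] * ad.tensor(keep_masks[k]) * (1.0 / scales[k])
                       for k, i in enumerate(kept_rows)])
    node_ind = np.stack(node_inds)
    emb = model.encode_tensors(masked, node_ind)
    memb = model.activation_tensors(emb)
    hard = memb.data.argmax(axis=1)
    for c in range(dataset.n_classes):
        if model.formulas.get(c) is not None:
            out[c] = project_node_explanation(model, c, memb, node_ind, hard)

    if ctx.get("anchor"):
        # prototype-only training signal of the frozen explainer, on
        # detached embeddings so only the prototypes move through this term
        ctx["anchor_loss"] = _prototype_objective(
            model, emb.detach(), preds[np.array(kept_rows)])
    return out


def _prototype_objective(model: ConceptModel, emb: Tensor, targets: np.ndarray):
    """Frozen-explainer loss in the prototypes only: logic-layer
    cross-entropy + soft-k-means distance (prototypes attracted to
    membership-weighted centroids — a stable, unique attractor) + a small
    cover term keeping every prototype near some embedding."""
    from .backbone import cross_entropy

    diff = emb.reshape((emb.shape[0], 1, model.q)) - \
        model.prototypes.reshape((1, model.m, model.q))
    d2 = (diff * diff).sum(axis=-1)
    memb = model.activation_tensors(emb)
    ce = cross_entropy(model.logic_logits(memb), targets)
    return ce + (memb * d2).sum(axis=1).mean() + 0.3 * d2.min(axis=0).mean()


def _edge_only_local(edge_scores: np.ndarray, sample_id: str, class_id: int,
                     layer: int, method: str):
    from .explainers import LocalExplanation

    return LocalExplanation(sample_id, class_id, layer, method,
                            edge_scores=edge_scores)


# -- training loops -----------------------------------------------------------


def _supervised_epochs(params: BackboneParams, dataset: GraphDataset,
                       labels: Optional[ClassExplanationLabel], cfg: TrainConfig,
                       epochs: int, state: TrainingState,
                       concept_ctx: Optional[dict] = None,
                       extra_params: Optional[List[Tensor]] = None):
    backbone = params.trainable()
    extra = extra_params or []
    opt = ad.Adam(backbone, lr=cfg.lr)
    # prototypes move at the explainer's own (faster) learning rate
    opt_extra = ad.Adam(extra, lr=cfg.glg.lr) if extra else None
    for _ in range(epochs):
        loss, comp = total_objective(params, dataset, labels, cfg, concept_ctx)
        grads = ad.grad(loss, backbone + extra)
        opt.step(grads[: len(backbone)])
        if opt_extra is not None:
            opt_extra.step(grads[len(backbone):])
        state.history.append(comp)
    return params


def train_ggnes(dataset: GraphDataset, labels: Optional[ClassExplanationLabel],
                cfg: TrainConfig) -> TrainingState:
    """Full training procedure.

    min/max/avg modes: train the plain classifier, then fine-tune it under
    the joint objective with the chosen aggregator.

    concept mode iterates three steps: (1) plain training; (2) fit the
    concept explainer on the model's local explanations; (3) fine-tune the
    backbone under the joint objective with M_c given by the formula
    projection — formula, logic layer and encoder frozen at their step-2
    values, prototypes re-initialized uniformly at random and updated
    (anchored to the embedding clusters) during the fine-tune.  Steps 2-3
    repeat until the prototypes move less than ``proto_tol`` between outer
    iterations or ``max_outer_iters`` is hit (then ``converged=False``).
    """
    if labels is not None:
        labels.validate_against(dataset)
    params, base_hist = train_baseline(dataset, epochs=cfg.epochs, lr=cfg.lr,
                                       hidden_dims=cfg.hidden_dims, seed=cfg.seed)
    state = TrainingState(backbone=params, config=cfg)
    state.history = [{"L_pred": v, "total": v} for v in base_hist.loss]

    if cfg.mode in ("min", "max", "avg"):
        _supervised_epochs(params, dataset, labels, cfg, cfg.supervised_epochs, state)
        state.backbone = params
        return state

    # concept mode
    rng = np.random.default_rng(cfg.seed + 1)
    prev_protos = None
    concept = None
    for it in range(cfg.max_outer_iters):
        if concept is None:
            # step 2: fit the concept explainer on the trained model's local
            # explanations.  Encoder, logic layer and formulas stay frozen at
            # these values for every later iteration (only the prototypes
            # remain learnable), which keeps the embedding space fixed so
            # prototype displacement across iterations is well-defined.
            preds = predict(params, dataset)
            locals_ = _detached_edge_locals(params, dataset, cfg, preds)
            concept = fit_glg(locals_, preds, cfg.n_prototypes, cfg.glg,
                              n_classes=dataset.n_classes)
        # step 3: re-initialize prototypes at random, fine-tune the backbone
        # under the full objective with the prototypes updating alongside
        concept.prototypes.data = rng.uniform(0, 1, concept.prototypes.shape)
        _supervised_epochs(params, dataset, labels, cfg, cfg.supervised_epochs,
                           state, concept_ctx={"model": concept, "anchor": True},
                           extra_params=[concept.prototypes])
        _refine_prototypes(params, dataset, cfg, concept)
        protos = concept.prototypes.data.copy()
        if prev_protos is not None:
            disp = float(np.max(np.linalg.norm(protos - prev_protos, axis=1)))
            state.prototype_displacements.append(disp)
            scale = _prototype_scale(protos)
            if disp < cfg.proto_tol * scale:
                state.n_outer_iters = it + 1
                state.backbone = params
                state.concept = concept
                return state
        prev_protos = protos
        state.concept = concept
    state.converged = False
    state.n_outer_iters = cfg.max_outer_iters
    state.backbone = params
    return state


def _prototype_scale(protos: np.ndarray) -> float:
    """Mean pairwise prototype distance; the natural displacement unit."""
    m = protos.shape[0]
    d = [np.linalg.norm(protos[i] - protos[j])
         for i in range(m) for j in range(i + 1, m)]
    return float(max(np.mean(d), 1e-12))


def _refine_prototypes(params, dataset, cfg, concept: ConceptModel, steps: int = 400):
    """Drive the prototypes to their fixed point for the *current* backbone.

    The joint fine-tune moves prototypes a little every epoch, but from a
    fresh random initialization they rarely cross the embedding space within
    one fine-tune; this cheap prototype-only phase (embeddings fixed)
    finishes the descent of the same prototype objective — the frozen logic
    layer's cross-entropy plus pull/cover distances.
    """
    preds = predict(params, dataset)
    locals_ = _detached_edge_locals(params, dataset, cfg, preds)
    subs, kept = [], []
    for i, loc in enumerate(locals_):
        g = binarize_explanation(loc, concept.top_fraction)
        if not g.degenerate:
            subs.append(g)
            kept.append(i)
    if not subs:
        return
    emb = ad.tensor(concept.embed_subgraphs(subs))
    targets = preds[np.array(kept)]
    opt = ad.Adam([concept.prototypes], lr=cfg.glg.lr)
    for _ in range(steps):
        loss = _prototype_objective(concept, emb, targets)
        opt.step(ad.grad(loss, [concept.prototypes]))


def _detached_edge_locals(params, dataset, cfg, preds):
    from .explainers import LocalExplanation

    a, x = dataset.adjacency_stack(), dataset.feature_stack()
    locals_: List[LocalExplanation] = [None] * len(dataset)
    from .explainers import default_layer
    layer = cfg.layer or default_layer(params)
    for c in sorted(set(preds)):
        idx = np.nonzero(preds == c)[0]
        _, et = batch_saliency(params, a[idx], x[idx], int(c), cfg.layer,
                               cfg.local_method, cfg.norm, need_node=False,
                               need_edge=True, create_graph=False)
        for pos, i in enumerate(idx):
            locals_[i] = LocalExplanation(dataset.samples[i].sample_id, int(c),
                                          layer, cfg.local_method,
                                          edge_scores=et.data[pos])
    return locals_


def global_explanations(params: BackboneParams, dataset: GraphDataset,
                        cfg: TrainConfig, concept: Optional[ConceptModel] = None
                        ) -> GlobalExplanation:
    """Detached per-class global explanations for reporting/evaluation."""
    mode = "avg" if cfg.mode == "concept" else cfg.mode
    node_t, edge_t = _class_globals(params, dataset, replace(cfg, mode=mode),
                                    need_node=True, need_edge=True,
                                    create_graph=False)
    out = GlobalExplanation(mode=cfg.mode, normalized=True)
    for c, t in node_t.items():
        out.node[c] = t.data if isinstance(t, Tensor) else t
    for c, t in edge_t.items():
        out.edge[c] = t.data if isinstance(t, Tensor) else t
    if cfg.mode == "concept" and concept is not None:
        preds = predict(params, dataset)
        locals_ = _detached_edge_locals(params, dataset, cfg, preds)
        subs = [binarize_explanation(l, concept.top_fraction) for l in locals_]
        subs = [g for g in subs if not g.degenerate]
        if subs:
            from .concepts import concept_global_node_explanation

            for c in range(dataset.n_classes):
                out.node[c] = concept_global_node_explanation(concept, subs, c)
    return out
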