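"""Model / Results surface for explanation-supervised graph classification.

Usage follows the fit-and-inspect idiom of statistical modelling packages::

    model = GlobalExplanationGCN(train_set, masks, mode="avg")
    res = model.fit(seed=0)
    print(res.summary())
    res.evaluate(test_set, masks)

The model object holds the data and configuration; ``fit`` runs the full
training procedure (plain classifier, then supervised fine-tuning — or the
three-step concept loop) and returns a results object carrying the learned
weights, the per-class global explanations, training history, metrics and
any extracted logic formulas.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .aggregation import GlobalExplanation
from .backbone import predict, predict_proba
from .concepts import concept_purity, fidelity, formula_accuracy
from .data import AtlasGraph, ClassExplanationLabel, GraphDataset
from .evaluation import (EvaluationReport, config_hash, evaluate_explanations,
                         evaluate_predictions)
from .training import (LossWeights, TrainConfig, TrainingState,
                       global_explanations, train_ggnes)


class GlobalExplanationGCN:
    """A GCN graph classifier whose global, per-class explanations are
    supervised by human masks during training.

    Parameters
    ----------
    dataset : GraphDataset
        Training samples on a fixed atlas.
    labels : ClassExplanationLabel, optional
        Per-class ground-truth node/edge masks; classes without masks still
        receive the consistency/sparsity regularizers.
    mode : str
        Global aggregator: ``"none"`` (plain classifier), ``"min"``,
        ``"max"``, ``"avg"``, or ``"concept"``.
    config : TrainConfig, optional
        Full configuration; keyword arguments below override its fields.
    """

    def __init__(self, dataset: GraphDataset, labels: Optional[ClassExplanationLabel] = None,
                 mode: str = "avg", config: Optional[TrainConfig] = None, **overrides):
        self.dataset = dataset
        self.labels = labels
        self.unsupervised = mode == "none"
        cfg = config or TrainConfig()
        cfg = replace(cfg, mode="avg" if mode == "none" else mode, **overrides)
        if self.unsupervised:
            cfg = replace(cfg, weights=LossWeights(0.0, 0.0, 0.0, 0.0),
                          supervised_epochs=0)
        self.config = cfg
        if labels is not None:
            labels.validate_against(dataset)

    @classmethod
    def from_arrays(cls, adjacency: np.ndarray, features: Optional[np.ndarray],
                    y: np.ndarray, node_masks: Optional[dict] = None,
                    edge_masks: Optional[dict] = None, **kwargs) -> "GlobalExplanationGCN":
        """Build directly from ``(Z,N,N)`` adjacency, optional ``(Z,N,d)``
        features (constant column when absent) and integer labels."""
        z, n = adjacency.shape[:2]
        if features is None:
            features = np.ones((z, n, 1))
        samples = [AtlasGraph(adjacency[i], features[i], int(y[i]), f"s{i:04d}")
                   for i in range(z)]
        dataset = GraphDataset(samples, int(np.max(y)) + 1)
        labels = None
        if node_masks or edge_masks:
            labels = ClassExplanationLabel(node_mask=dict(node_masks or {}),
                                           edge_mask=dict(edge_masks or {}))
        return cls(dataset, labels, **kwargs)

    def fit(self, seed: Optional[int] = None, **overrides) -> "GGNESResults":
        cfg = replace(self.config, **overrides)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        state = train_ggnes(self.dataset, self.labels, cfg)
        return GGNESResults(self, state)


class GGNESResults:
    """Fitted state: backbone weights, explanations, history, diagnostics."""

    def __init__(self, model: GlobalExplanationGCN, state: TrainingState):
        self.model = model
        self.state = state
        self.config = state.config
        self.backbone = state.backbone
        self.concept = state.concept
        self.converged = state.converged
        self._train_globals: Optional[GlobalExplanation] = None

    # -- prediction -----------------------------------------------------------
    def predict(self, dataset: Optional[GraphDataset] = None) -> np.ndarray:
        return predict(self.backbone, dataset or self.model.dataset)

    def predict_proba(self, dataset: Optional[GraphDataset] = None) -> np.ndarray:
        return predict_proba(self.backbone, dataset or self.model.dataset)

    # -- explanations ---------------------------------------------------------
    def explanations(self, dataset: Optional[GraphDataset] = None) -> GlobalExplanation:
        """Per-class global node/edge explanations recomputed on a split."""
        dataset = dataset or self.model.dataset
        return global_explanations(self.backbone, dataset, self.config, self.concept)

    @property
    def formulas(self):
        return self.concept.formulas if self.concept is not None else None

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, dataset: Optional[GraphDataset] = None,
                 labels: Optional[ClassExplanationLabel] = None) -> EvaluationReport:
        dataset = dataset or self.model.dataset
        labels = labels if labels is not None else self.model.labels
        acc, auc = evaluate_predictions(self.backbone, dataset)
        expl = evaluate_explanations(self.explanations(dataset), labels)
        rep = EvaluationReport(acc=acc, auc=auc, explanation=expl,
                               seed=self.config.seed,
                               config_hash=config_hash(self.config))
        if self.concept is not None:
            from .training import _detached_edge_locals
            from .concepts import binarize_explanation

            preds = self.predict(dataset)
            locals_ = _detached_edge_locals(self.backbone, dataset, self.config, preds)
            subs, kept = [], []
            for i, loc in enumerate(locals_):
                g = binarize_explanation(loc, self.concept.top_fraction)
                if not g.degenerate:
                    subs.append(g)
                    kept.append(i)
            if subs:
                assign = self.concept.assign(subs)
                fp = self.concept.formula_predictions(assign)
                rep.fidelity = fidelity(fp, preds[kept])
                rep.formula_accuracy = formula_accuracy(fp, dataset.labels()[kept])
                rep.purity_mean, rep.purity_sd = concept_purity(
                    assign, dataset.labels()[kept])
        return rep

    # -- presentation ---------------------------------------------------------
    def summary(self) -> str:
        rep = self.evaluate()
        cfg = self.config
        w = cfg.weights
        lines = [
            "Global Explanation Supervision — GCN Results",
            "=" * 52,
            f"mode: {'none' if self.model.unsupervised else cfg.mode:<12}"
            f" local explainer: {cfg.local_method}",
            f"layers: {len(cfg.hidden_dims)} (dims {list(cfg.hidden_dims)})"
            f"  epochs: {cfg.epochs}+{cfg.supervised_epochs}  lr: {cfg.lr}",
            f"alpha_n={w.alpha_n} alpha_e={w.alpha_e} beta={w.beta} "
            f"gamma={w.gamma} dist={w.dist_kind}  seed={cfg.seed}",
            "-" * 52,
            f"train ACC: {rep.acc:.3f}" + (f"   AUC: {rep.auc:.3f}" if rep.auc else ""),
        ]
        for key in ("node_mse", "node_mae", "edge_mse", "edge_mae"):
            if key in rep.explanation:
                lines.append(f"{key:>9}: {rep.explanation[key]:.3f}")
        if self.concept is not None:
            lines.append(f" fidelity: {rep.fidelity:.3f}   formula acc: "
                         f"{rep.formula_accuracy:.3f}")
            lines.append(f"   purity: {rep.purity_mean:.3f} ± {rep.purity_sd:.3f}"
                         f"   converged: {self.converged} "
                         f"({self.state.n_outer_iters} outer iters)")
            for c, f in sorted(self.formulas.items()):
                lines.append(f"  class {c} ⇔ {f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return (f"<GGNESResults mode={self.config.mode} "
                f"seed={self.config.seed} converged={self.converged}>")
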