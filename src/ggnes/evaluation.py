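"""Prediction and explanation-quality metrics, and the multi-mode runner."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score

from .aggregation import GlobalExplanation
from .backbone import BackboneParams, predict_proba
from .data import ClassExplanationLabel, GraphDataset


def evaluate_predictions(params: BackboneParams, dataset: GraphDataset):
    """(ACC, AUC) on a split; AUC is one-vs-rest macro for C>2 and None for
    a single-class split."""
    probs = predict_proba(params, dataset)
    y = dataset.labels()
    acc = float(accuracy_score(y, probs.argmax(axis=1)))
    if len(np.unique(y)) < 2:
        return acc, None
    if dataset.n_classes == 2:
        auc = float(roc_auc_score(y, probs[:, 1]))
    else:
        auc = float(roc_auc_score(y, probs, multi_class="ovr", average="macro"))
    return acc, auc


def evaluate_explanations(globals_: GlobalExplanation,
                          labels: Optional[ClassExplanationLabel]) -> Dict[str, float]:
    """Per-class node/edge MSE and MAE against the human masks, plus means.

    Edge metrics are computed over off-diagonal entries only (the diagonal
    is structurally zero on both sides).
    """
    out: Dict[str, float] = {}
    if labels is None or not labels.annotated_classes:
        return out
    node_mse, node_mae, edge_mse, edge_mae = [], [], [], []
    for c in labels.annotated_classes:
        if c in labels.node_mask and c in globals_.node:
            d = np.asarray(globals_.node[c]) - labels.node_mask[c]
            out[f"node_mse_c{c}"] = float((d**2).mean())
            out[f"node_mae_c{c}"] = float(np.abs(d).mean())
            node_mse.append(out[f"node_mse_c{c}"])
            node_mae.append(out[f"node_mae_c{c}"])
        if c in labels.edge_mask and c in globals_.edge:
            e = np.asarray(globals_.edge[c])
            n = e.shape[0]
            off = ~np.eye(n, dtype=bool)
            d = (e - labels.edge_mask[c])[off]
            out[f"edge_mse_c{c}"] = float((d**2).mean())
            out[f"edge_mae_c{c}"] = float(np.abs(d).mean())
            edge_mse.append(out[f"edge_mse_c{c}"])
            edge_mae.append(out[f"edge_mae_c{c}"])
    for name, vals in (("node_mse", node_mse), ("node_mae", node_mae),
                       ("edge_mse", edge_mse), ("edge_mae", edge_mae)):
        if vals:
            out[name] = float(np.mean(vals))
    return out


@dataclass
class EvaluationReport:
    """Serializable record of one trained run's quality."""

    acc: float
    auc: Optional[float]
    explanation: Dict[str, float] = field(default_factory=dict)
    fidelity: Optional[float] = None
    formula_accuracy: Optional[float] = None
    purity_mean: Optional[float] = None
    purity_sd: Optional[float] = None
    seed: int = 0
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls(**json.loads(s))


def config_hash(cfg) -> str:
    from dataclasses import is_dataclass

    def enc(o):
        if is_dataclass(o):
            return asdict(o)
        return str(o)

    return hashlib.sha256(json.dumps(enc(cfg), sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def stratified_split(dataset: GraphDataset, test_fraction: float = 0.2, seed: int = 0):
    """Class-stratified train/test index split, deterministic given seed."""
    rng = np.random.default_rng(seed)
    y = dataset.labels()
    train_idx, test_idx = [], []
    for c in range(dataset.n_classes):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        k = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:k])
        train_idx.extend(idx[k:])
    return sorted(train_idx), sorted(test_idx)


def run_experiment(dataset: GraphDataset, labels: Optional[ClassExplanationLabel],
                   modes: List[str], n_seeds: int = 5, test_fraction: float = 0.2,
                   base_config=None) -> pd.DataFrame:
    """Train and evaluate every mode x seed; returns per-seed rows plus one
    mean row per mode (columns mirror an ACC/AUC/MSE/MAE comparison table).

    ``modes`` may include ``"none"`` (no supervision; the plain classifier).
    """
    from .model import GlobalExplanationGCN

    rows = []
    for mode in modes:
        for seed in range(n_seeds):
            tr, te = stratified_split(dataset, test_fraction, seed)
            model = GlobalExplanationGCN(dataset.subset(tr), labels, mode=mode,
                                         config=base_config)
            res = model.fit(seed=seed)
            rep = res.evaluate(dataset.subset(te), labels)
            row = {"mode": mode, "seed": seed, "ACC": rep.acc, "AUC": rep.auc}
            for key in ("node_mse", "node_mae", "edge_mse", "edge_mae"):
                row[key] = rep.explanation.get(key)
            rows.append(row)
    frame = pd.DataFrame(rows)
    means = (frame.drop(columns="seed").groupby("mode", sort=False)
             .mean(numeric_only=True).reset_index())
    means.insert(1, "seed", "mean")
    return pd.concat([frame, means], ignore_index=True)
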