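"""Data model and I/O for fixed-atlas graph-classification datasets.

Every sample lives on the same ordered set of N nodes (an *atlas*, e.g. the
68 cortical regions of a brain parcellation), so a per-class node mask of
length N and an N x N edge mask are well-defined across samples.  Graphs are
undirected and weighted; adjacency diagonals are zero.

Two on-disk layouts are supported:

``npz_bundle``
    one ``.npz`` archive with arrays ``adjacency [Z,N,N]``,
    ``features [Z,N,d_in]``, ``labels [Z]``, optional ``node_mask [C,N]`` /
    ``edge_mask [C,N,N]``, plus a JSON manifest stored under ``manifest``.

``csv_dir``
    a directory of per-sample ``sample_<id>_adj.csv`` dense matrices, a
    ``labels.csv`` (sample_id,label), and per-class ``node_mask_c<k>.csv`` /
    ``edge_mask_c<k>.csv`` files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8


class DatasetError(ValueError):
    """Raised on malformed datasets or mask files."""


@dataclass
class AtlasGraph:
    """One sample: weighted adjacency + node features on the shared atlas."""

    adjacency: np.ndarray  # (N, N) nonnegative, symmetric, zero diagonal
    features: np.ndarray  # (N, d_in)
    label: int
    sample_id: str

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DatasetError(f"adjacency must be square, got {a.shape}")
        if np.abs(a - a.T).max(initial=0.0) > SYMMETRY_TOL:
            raise DatasetError(f"adjacency not symmetric (sample {self.sample_id})")
        if np.abs(np.diag(a)).max(initial=0.0) > SYMMETRY_TOL:
            raise DatasetError(f"adjacency diagonal must be zero (sample {self.sample_id})")
        if a.min(initial=0.0) < -SYMMETRY_TOL:
            raise DatasetError(f"adjacency must be nonnegative (sample {self.sample_id})")
        # mirror the upper triangle so both halves agree exactly
        upper = np.triu(a, k=1)
        self.adjacency = upper + upper.T
        if self.features.ndim == 1:
            self.features = self.features[:, None]
        if self.features.shape[0] != a.shape[0]:
            raise DatasetError("features row count must equal atlas size")
        if self.features.shape[1] < 1:
            raise DatasetError("d_in must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GraphDataset:
    """Ordered collection of :class:`AtlasGraph` sharing one atlas."""

    samples: list
    n_classes: int
    atlas_labels: Optional[list] = None

    def __post_init__(self):
        if not self.samples:
            raise DatasetError("dataset must contain at least one sample")
        n = self.samples[0].n_nodes
        for s in self.samples:
            if s.n_nodes != n:
                raise DatasetError("atlas size inconsistent")
            if not (0 <= s.label < self.n_classes):
                raise DatasetError(f"label {s.label} outside 0..{self.n_classes - 1}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DatasetError("sample_ids must be unique")
        if self.atlas_labels is not None and len(self.atlas_labels) != n:
            raise DatasetError("atlas_labels length must equal atlas size")

    def require_all_classes(self):
        """Full-dataset contract (enforced on load/save): every declared
        class has at least one sample.  Evaluation splits may be narrower."""
        present = {s.label for s in self.samples}
        if present != set(range(self.n_classes)):
            raise DatasetError("every class needs at least one sample")

    @property
    def n_nodes(self) -> int:
        return self.samples[0].n_nodes

    @property
    def d_in(self) -> int:
        return self.samples[0].features.shape[1]

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def indices_of_class(self, c: int) -> np.ndarray:
        return np.nonzero(self.labels() == c)[0]

    def subset(self, idx) -> "GraphDataset":
        return GraphDataset([self.samples[i] for i in idx], self.n_classes, self.atlas_labels)

    def adjacency_stack(self) -> np.ndarray:
        return np.stack([s.adjacency for s in self.samples])

    def feature_stack(self) -> np.ndarray:
        return np.stack([s.features for s in self.samples])


@dataclass
class ClassExplanationLabel:
    """Per-class ground-truth masks ("human annotation"), unique per class.

    ``node_mask[c]`` is a length-N vector in [0,1]; ``edge_mask[c]`` an
    N x N symmetric matrix in [0,1] with zero diagonal.  A class may carry
    either, both, or (if unannotated) neither.
    """

    node_mask: dict = field(default_factory=dict)  # class -> (N,)
    edge_mask: dict = field(default_factory=dict)  # class -> (N, N)

    def __post_init__(self):
        for c, m in self.node_mask.items():
            m = np.asarray(m, dtype=np.float64)
            if m.ndim != 1 or m.min() < 0 or m.max(initial=0) > 1:
                raise DatasetError(f"node mask for class {c} must be a vector in [0,1]")
            self.node_mask[c] = m
        for c, e in self.edge_mask.items():
            e = np.asarray(e, dtype=np.float64)
            if e.ndim != 2 or e.shape[0] != e.shape[1]:
                raise DatasetError(f"edge mask for class {c} must be square")
            if np.abs(e - e.T).max(initial=0.0) > SYMMETRY_TOL:
                raise DatasetError(f"edge mask for class {c} not symmetric")
            if np.abs(np.diag(e)).max(initial=0.0) > 0:
                raise DatasetError(f"edge mask for class {c} has nonzero diagonal")
            if e.min() < 0 or e.max(initial=0) > 1:
                raise DatasetError(f"edge mask for class {c} must lie in [0,1]")
            self.edge_mask[c] = e

    @property
    def annotated_classes(self):
        return sorted(set(self.node_mask) | set(self.edge_mask))

    def validate_against(self, dataset: GraphDataset):
        n, c_max = dataset.n_nodes, dataset.n_classes
        for c in self.annotated_classes:
            if not (0 <= c < c_max):
                raise DatasetError("mask for undeclared class")
        for c, m in self.node_mask.items():
            if m.shape != (n,):
                raise DatasetError(f"node mask for class {c} has wrong length")
        for c, e in self.edge_mask.items():
            if e.shape != (n, n):
                raise DatasetError(f"edge mask for class {c} has wrong shape")


# -- I/O ----------------------------------------------------------------------


def save_dataset(dataset: GraphDataset, labels: Optional[ClassExplanationLabel],
                 path, fmt: str = "npz_bundle") -> None:
    """Write a dataset (and optional masks) to ``path`` in the given layout."""
    path = Path(path)
    dataset.require_all_classes()
    if labels is not None:
        labels.validate_against(dataset)
    manifest = {
        "N": dataset.n_nodes,
        "C": dataset.n_classes,
        "Z": len(dataset),
        "d_in": dataset.d_in,
        "atlas_labels": dataset.atlas_labels,
        "sample_ids": [s.sample_id for s in dataset],
        "annotated_classes": labels.annotated_classes if labels else [],
    }
    if fmt == "npz_bundle":
        arrays = {
            "adjacency": dataset.adjacency_stack(),
            "features": dataset.feature_stack(),
            "labels": dataset.labels(),
            "manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
        }
        if labels is not None and labels.node_mask:
            classes = sorted(labels.node_mask)
            arrays["node_mask"] = np.stack([labels.node_mask[c] for c in classes])
            arrays["node_mask_classes"] = np.array(classes, dtype=int)
        if labels is not None and labels.edge_mask:
            classes = sorted(labels.edge_mask)
            arrays["edge_mask"] = np.stack([labels.edge_mask[c] for c in classes])
            arrays["edge_mask_classes"] = np.array(classes, dtype=int)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **arrays)
    elif fmt == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for s in dataset:
            pd.DataFrame(s.adjacency).to_csv(path / f"sample_{s.sample_id}_adj.csv",
                                             index=False, header=False)
            pd.DataFrame(s.features).to_csv(path / f"sample_{s.sample_id}_feat.csv",
                                            index=False, header=False)
        pd.DataFrame({"sample_id": [s.sample_id for s in dataset],
                      "label": dataset.labels()}).to_csv(path / "labels.csv", index=False)
        if labels is not None:
            for c, m in labels.node_mask.items():
                pd.DataFrame(m[None, :]).to_csv(path / f"node_mask_c{c}.csv",
                                                index=False, header=False)
            for c, e in labels.edge_mask.items():
                pd.DataFrame(e).to_csv(path / f"edge_mask_c{c}.csv",
                                       index=False, header=False)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_dataset(path, fmt: str = "npz_bundle"):
    """Load a dataset written by :func:`save_dataset`.

    Returns ``(GraphDataset, ClassExplanationLabel or None)``.
    """
    path = Path(path)
    if fmt == "npz_bundle":
        with np.load(path) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            adj, feat, lab = z["adjacency"], z["features"], z["labels"]
            node_mask = {}
            edge_mask = {}
            if "node_mask" in z:
                for c, m in zip(z["node_mask_classes"], z["node_mask"]):
                    node_mask[int(c)] = m
            if "edge_mask" in z:
                for c, e in zip(z["edge_mask_classes"], z["edge_mask"]):
                    edge_mask[int(c)] = e
        ids = manifest["sample_ids"]
        samples = [AtlasGraph(adj[i], feat[i], int(lab[i]), ids[i]) for i in range(len(ids))]
        dataset = GraphDataset(samples, manifest["C"], manifest.get("atlas_labels"))
    elif fmt == "csv_dir":
        manifest = json.loads((path / "manifest.json").read_text())
        lab = pd.read_csv(path / "labels.csv", dtype={"sample_id": str})
        samples = []
        for sid, label in zip(lab["sample_id"], lab["label"]):
            a = pd.read_csv(path / f"sample_{sid}_adj.csv", header=None).to_numpy(float)
            fpath = path / f"sample_{sid}_feat.csv"
            f = (pd.read_csv(fpath, header=None).to_numpy(float)
                 if fpath.exists() else np.ones((a.shape[0], 1)))
            samples.append(AtlasGraph(a, f, int(label), str(sid)))
        dataset = GraphDataset(samples, manifest["C"], manifest.get("atlas_labels"))
        node_mask, edge_mask = {}, {}
        for p in sorted(path.glob("node_mask_c*.csv")):
            c = int(p.stem.rsplit("c", 1)[1])
            node_mask[c] = pd.read_csv(p, header=None).to_numpy(float).ravel()
        for p in sorted(path.glob("edge_mask_c*.csv")):
            c = int(p.stem.rsplit("c", 1)[1])
            edge_mask[c] = pd.read_csv(p, header=None).to_numpy(float)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    dataset.require_all_classes()
    labels_obj = None
    if node_mask or edge_mask:
        labels_obj = ClassExplanationLabel(node_mask=node_mask, edge_mask=edge_mask)
        labels_obj.validate_against(dataset)
    return dataset, labels_obj
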