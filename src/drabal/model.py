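"""The DRABAL multi-label model.

One binary base classifier is trained per assay, in topological order of the
label-dependency DAG.  Each node's design matrix is the compound feature
matrix augmented with one probability-score column per parent assay: the
parent classifier's predicted probability of activity for every compound,
observed or not.  Those score columns are the feedback mechanism — they
propagate information down the DAG and stand in for missing parent labels, so
no label is ever coerced.  Rows whose own label is missing for an assay are
excluded from that assay's training targets but still receive parent scores
for use by descendant classifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import ACTIVE, MISSING, MultiLabelDataset
from .exceptions import DegenerateLabelError, ParameterError
from .structure import LabelDependencyGraph

logger = logging.getLogger(__name__)

_FAMILIES = ("random_forest", "svm_rbf", "knn")

#: Default hyperparameters per base-classifier family.
_FAMILY_DEFAULTS: dict[str, dict] = {
    "random_forest": {"n_estimators": 500},
    "knn": {"n_neighbors": 3},
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
}


def node_random_state(seed: int, node_index: int) -> int:
    """Deterministic per-node seed; shared with the baseline fitters so that
    a DRABAL model with an edgeless graph is bit-identical to binary relevance."""
    return (seed * 1_000_003 + 7919 * node_index + 1) % (2**31)


@dataclass
class BaseClassifierSpec:
    """Family + hyperparameters of the per-assay base classifier.

    Supported families: ``random_forest`` (500 trees), ``knn`` (K = 3) and
    ``svm_rbf`` (RBF kernel, default cost, Platt-calibrated probabilities).
    """

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        self.hyperparameters = {**_FAMILY_DEFAULTS[self.family], **self.hyperparameters}

    def build(self, random_state: int):
        """Instantiate an unfitted scikit-learn estimator for one assay."""
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=random_state,
                                          **self.hyperparameters)
        if self.family == "knn":
            return KNeighborsClassifier(**self.hyperparameters)
        return SVC(kernel="rbf", probability=True, random_state=random_state,
                   **self.hyperparameters)

    def to_dict(self) -> dict:
        return {"family": self.family, "hyperparameters": self.hyperparameters,
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaseClassifierSpec":
        return cls(family=d["family"], hyperparameters=dict(d["hyperparameters"]),
                   seed=int(d["seed"]))


@dataclass
class NodeClassifier:
    """A fitted base model for one assay plus its wiring in the DAG."""

    assay_id: str
    parent_ids: list[str]
    estimator: object
    training_mask: np.ndarray  # row indices with an observed label for this assay

    @property
    def n_features_in(self) -> int:
        return int(self.estimator.n_features_in_)


def _positive_proba(estimator, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class, robust to classes_ ordering."""
    if X.shape[0] == 0:
        return np.zeros(0)
    proba = estimator.predict_proba(X)
    pos_col = int(np.flatnonzero(estimator.classes_ == 1)[0])
    return proba[:, pos_col]


class DrabalModel:
    """Topologically ordered per-assay classifiers with parent-score features.

    Parameters
    ----------
    graph:
        Label-dependency DAG over the dataset's assay ids.
    base:
        Base-classifier family and hyperparameters shared by all nodes.
    threshold:
        Probability cut for class calls; scores >= threshold map to +1.
    parent_scores:
        ``"in_sample"`` (parent scores are the fitted parent's in-sample
        predicted probabilities) or ``"out_of_fold"`` (internal k-fold
        predictions on observed rows, curbing optimistic leakage).
    """

    def __init__(
        self,
        graph: LabelDependencyGraph,
        base: BaseClassifierSpec | None = None,
        threshold: float = 0.5,
        parent_scores: str = "in_sample",
        oof_folds: int = 5,
    ):
        if parent_scores not in ("in_sample", "out_of_fold"):
            raise ParameterError("parent_scores must be 'in_sample' or 'out_of_fold'")
        self.graph = graph
        self.base = base or BaseClassifierSpec()
        self.threshold = float(threshold)
        self.parent_scores = parent_scores
        self.oof_folds = int(oof_folds)
        self.order_: list[str] | None = None
        self.node_classifiers_: dict[str, NodeClassifier] = {}
        self.assay_ids_: list[str] | None = None
        self.n_features_: int | None = None

    # ------------------------------------------------------------------ fit
    def fit(self, dataset: MultiLabelDataset) -> "DrabalModel":
        if set(dataset.assay_ids) != set(self.graph.nodes):
            raise ParameterError("dataset and graph assay ids differ")
        self.assay_ids_ = list(dataset.assay_ids)
        self.n_features_ = dataset.n_features
        self.order_ = self.graph.topological_order()
        col = {a: j for j, a in enumerate(dataset.assay_ids)}

        X, labels = dataset.features, dataset.labels
        M = dataset.n_compounds
        train_scores = np.zeros((M, dataset.n_assays))
        self.node_classifiers_ = {}

        for assay in self.order_:
            j = col[assay]
            parents = sorted(self.graph.parents_of(assay))
            design = self._augment(X, train_scores, [col[p] for p in parents])
            obs = np.flatnonzero(labels[:, j] != MISSING)
            y = (labels[obs, j] == ACTIVE).astype(int)
            if y.size == 0 or y.min() == y.max():
                raise DegenerateLabelError(assay)
            est = self.base.build(node_random_state(self.base.seed, j))
            est.fit(design[obs], y)
            train_scores[:, j] = self._in_sample_scores(est, design, obs, y)
            self.node_classifiers_[assay] = NodeClassifier(
                assay_id=assay, parent_ids=parents, estimator=est, training_mask=obs
            )
        self._train_scores_ = train_scores  # kept for impute_missing_labels
        return self

    def _in_sample_scores(self, est, design: np.ndarray, obs: np.ndarray,
                          y: np.ndarray) -> np.ndarray:
        """Scores for every row from a just-fitted node (feedback columns)."""
        scores = _positive_proba(est, design)
        if self.parent_scores == "out_of_fold" and obs.size >= self.oof_folds:
            kf = KFold(self.oof_folds, shuffle=True,
                       random_state=node_random_state(self.base.seed, 0))
            oof = np.empty(obs.size)
            for tr, te in kf.split(obs):
                if len(np.unique(y[tr])) < 2:
                    oof[te] = y[tr].mean()
                    continue
                fold_est = clone(est)
                fold_est.fit(design[obs[tr]], y[tr])
                oof[te] = _positive_proba(fold_est, design[obs[te]])
            scores = scores.copy()
            scores[obs] = oof
        return scores

    @staticmethod
    def _augment(X: np.ndarray, scores: np.ndarray,
                 parent_cols: Sequence[int]) -> np.ndarray:
        if not parent_cols:
            return X
        return np.hstack([X, scores[:, list(parent_cols)]])

    # -------------------------------------------------------------- predict
    def _check_fitted(self) -> None:
        if self.order_ is None:
            raise ParameterError("model is not fitted")

    def _score_all(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ParameterError(
                f"expected {self.n_features_} feature columns, got {X.shape}"
            )
        col = {a: j for j, a in enumerate(self.assay_ids_)}
        out = np.zeros((X.shape[0], len(self.assay_ids_)))
        if X.shape[0] == 0:
            return out
        for assay in self.order_:
            node = self.node_classifiers_[assay]
            design = self._augment(X, out, [col[p] for p in node.parent_ids])
            out[:, col[assay]] = _positive_proba(node.estimator, design)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """m x N matrix of activity probabilities, computed node-by-node in
        topological order with each node consuming its parents' fresh scores."""
        return self._score_all(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """m x N class calls in {+1, -1}: +1 where score >= threshold."""
        proba = self.predict_proba(X)
        return np.where(proba >= self.threshold, 1, -1).astype(np.int8)

    def parent_score_columns(self, node: str, X: np.ndarray) -> np.ndarray:
        """m x |parents| matrix of parent activity scores for ``node``.

        Each column is the parent classifier's predicted probability, itself
        computed recursively from that parent's own parents (memoized)."""
        self._check_fitted()
        if node not in self.node_classifiers_:
            raise ParameterError(f"unknown node {node!r}")
        X = np.asarray(X, dtype=float)
        memo: dict[str, np.ndarray] = {}

        def score(a: str) -> np.ndarray:
            if a not in memo:
                nc = self.node_classifiers_[a]
                cols = [score(p) for p in nc.parent_ids]
                design = np.hstack([X] + [c[:, None] for c in cols]) if cols else X
                memo[a] = _positive_proba(nc.estimator, design)
            return memo[a]

        parents = self.node_classifiers_[node].parent_ids
        if not parents:
            return np.zeros((X.shape[0], 0))
        return np.column_stack([score(p) for p in parents])

    def impute_missing_labels(self, dataset: MultiLabelDataset) -> np.ndarray:
        """M x N score matrix: observed +1 -> 1, observed -1 -> 0, missing ->
        the node classifier's predicted activity probability."""
        self._check_fitted()
        scores = self.predict_proba(dataset.features)
        out = scores.copy()
        out[dataset.labels == ACTIVE] = 1.0
        out[dataset.labels == -1] = 0.0
        return out

    def screen(self, X: np.ndarray, compound_ids: Sequence[str],
               top_k: int) -> pd.DataFrame:
        """Rank compounds per assay by predicted activity score.

        Returns a tidy frame (assay_id, rank, compound_id, score) holding the
        ``top_k`` compounds per assay; ties broken by ascending compound id.
        """
        if top_k < 1:
            raise ParameterError("top_k must be >= 1")
        if len(compound_ids) != np.asarray(X).shape[0]:
            raise ParameterError("compound_ids length must match rows of X")
        proba = self.predict_proba(X)
        rows = []
        cids = np.asarray(compound_ids, dtype=object)
        for j, assay in enumerate(self.assay_ids_):
            order = sorted(range(len(cids)), key=lambda i: (-proba[i, j], cids[i]))
            for rank, i in enumerate(order[:top_k], start=1):
                rows.append({"assay_id": assay, "rank": rank,
                             "compound_id": cids[i], "score": float(proba[i, j])})
        return pd.DataFrame(rows, columns=["assay_id", "rank", "compound_id", "score"])

    # ------------------------------------------------------------ accounting
    @property
    def n_added_feature_columns(self) -> int:
        """Total score columns added across nodes (= number of DAG edges)."""
        self._check_fitted()
        return sum(len(nc.parent_ids) for nc in self.node_classifiers_.values())

    # ---------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        """Write a reloadable bundle: graph edge list, config JSON and one
        serialized base model per node.  Reload reproduces predict_proba
        bit-identically."""
        self._check_fitted()
        d = Path(directory)
        (d / "models").mkdir(parents=True, exist_ok=True)
        self.graph.to_files(d / "graph_edges.tsv", d / "graph_meta.json")
        node_files = {}
        for k, assay in enumerate(self.assay_ids_):
            fname = f"models/node_{k}.joblib"
            joblib.dump(self.node_classifiers_[assay].estimator, d / fname)
            node_files[assay] = fname
        config = {
            "assay_ids": self.assay_ids_,
            "order": self.order_,
            "threshold": self.threshold,
            "parent_scores": self.parent_scores,
            "n_features": self.n_features_,
            "base": self.base.to_dict(),
            "node_files": node_files,
            "parents": {a: self.node_classifiers_[a].parent_ids
                        for a in self.assay_ids_},
            "training_mask": {a: self.node_classifiers_[a].training_mask.tolist()
                              for a in self.assay_ids_},
        }
        (d / "config.json").write_text(json.dumps(config, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "DrabalModel":
        d = Path(directory)
        config = json.loads((d / "config.json").read_text())
        graph = LabelDependencyGraph.from_files(d / "graph_edges.tsv",
                                                d / "graph_meta.json")
        model = cls(graph, BaseClassifierSpec.from_dict(config["base"]),
                    threshold=config["threshold"],
                    parent_scores=config["parent_scores"])
        model.assay_ids_ = config["assay_ids"]
        model.order_ = config["order"]
        model.n_features_ = config["n_features"]
        model.node_classifiers_ = {
            a: NodeClassifier(
                assay_id=a,
                parent_ids=config["parents"][a],
                estimator=joblib.load(d / config["node_files"][a]),
                training_mask=np.asarray(config["training_mask"][a], dtype=int),
            )
            for a in config["assay_ids"]
        }
        return model


def fit(dataset: MultiLabelDataset, graph: LabelDependencyGraph,
        base: BaseClassifierSpec | None = None, **kwargs) -> DrabalModel:
    """Functional entry point: construct and fit a :class:`DrabalModel`."""
    return DrabalModel(graph, base, **kwargs).fit(dataset)
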