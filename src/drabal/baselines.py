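"""Reference multi-label baselines: binary relevance and classifier chains.

Binary relevance (BR) trains one independent classifier per assay on the rows
whose label for that assay is observed.  Classifier chains (CC) extend each
model's features with information from the labels earlier in a chosen chain
order; two missing-label policies are supported:

``as_negative`` (CC-MLE)
    every missing label is coerced to inactive before chaining, and the extra
    training columns carry the (coerced) hard labels;
``score_impute``
    no label is coerced; the extra columns carry the predecessor models'
    predicted activity probabilities, exactly as DRABAL shares scores.

At prediction time the chain always feeds predecessor predicted
probabilities forward, keeping train/test feature semantics aligned with the
probabilistic reading.  SVM bases expose Platt-calibrated probabilities so
chain features and thresholds are comparable across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import ACTIVE, INACTIVE, MISSING, MultiLabelDataset
from .exceptions import DegenerateLabelError, ParameterError
from .model import BaseClassifierSpec, _positive_proba, node_random_state

logger = logging.getLogger(__name__)


@dataclass
class ChainSpec:
    """Order, missing-label policy and base classifier of one chain."""

    order: list[str]
    missing_policy: str = "score_impute"  # or "as_negative" (CC-MLE)
    base: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)

    def __post_init__(self) -> None:
        if self.missing_policy not in ("as_negative", "score_impute"):
            raise ParameterError("missing_policy must be 'as_negative' or 'score_impute'")
        if len(set(self.order)) != len(self.order):
            raise ParameterError("chain order must not repeat assays")


class BinaryRelevanceModel:
    """One independent classifier per assay, trained on its observed rows."""

    def __init__(self, base: BaseClassifierSpec | None = None, threshold: float = 0.5):
        self.base = base or BaseClassifierSpec()
        self.threshold = float(threshold)
        self.estimators_: dict[str, object] = {}
        self.assay_ids_: list[str] | None = None
        self.training_masks_: dict[str, np.ndarray] = {}

    def fit(self, dataset: MultiLabelDataset) -> "BinaryRelevanceModel":
        self.assay_ids_ = list(dataset.assay_ids)
        X, labels = dataset.features, dataset.labels
        for j, assay in enumerate(dataset.assay_ids):
            obs = np.flatnonzero(labels[:, j] != MISSING)
            y = (labels[obs, j] == ACTIVE).astype(int)
            if y.size == 0 or y.min() == y.max():
                raise DegenerateLabelError(assay)
            est = self.base.build(node_random_state(self.base.seed, j))
            est.fit(X[obs], y)
            self.estimators_[assay] = est
            self.training_masks_[assay] = obs
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.assay_ids_ is None:
            raise ParameterError("model is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.assay_ids_)))
        for j, assay in enumerate(self.assay_ids_):
            out[:, j] = _positive_proba(self.estimators_[assay], X)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict_proba(X) >= self.threshold, 1, -1).astype(np.int8)


class ClassifierChainModel:
    """A single classifier chain over all assays in ``spec.order``.

    The i-th model in the chain consumes the d raw features plus i-1 extra
    columns from its predecessors (hard coerced labels for ``as_negative``
    training, predicted probabilities for ``score_impute`` and always
    probabilities at prediction time).
    """

    def __init__(self, spec: ChainSpec, threshold: float = 0.5):
        self.spec = spec
        self.threshold = float(threshold)
        self.estimators_: dict[str, object] = {}
        self.assay_ids_: list[str] | None = None
        self.n_features_in_: dict[str, int] = {}

    def fit(self, dataset: MultiLabelDataset) -> "ClassifierChainModel":
        if set(self.spec.order) != set(dataset.assay_ids):
            raise ParameterError("chain order must be a permutation of the assay ids")
        self.assay_ids_ = list(dataset.assay_ids)
        col = {a: j for j, a in enumerate(dataset.assay_ids)}
        X = dataset.features
        labels = dataset.labels.copy()
        if self.spec.missing_policy == "as_negative":
            labels[labels == MISSING] = INACTIVE

        M = dataset.n_compounds
        extra = np.zeros((M, 0))
        for assay in self.spec.order:
            j = col[assay]
            design = np.hstack([X, extra]) if extra.shape[1] else X
            obs = np.flatnonzero(labels[:, j] != MISSING)
            y = (labels[obs, j] == ACTIVE).astype(int)
            if y.size == 0 or y.min() == y.max():
                raise DegenerateLabelError(assay)
            est = self.spec.base.build(node_random_state(self.spec.base.seed, j))
            est.fit(design[obs], y)
            self.estimators_[assay] = est
            self.n_features_in_[assay] = design.shape[1]
            if self.spec.missing_policy == "as_negative":
                new_col = (labels[:, j] == ACTIVE).astype(float)
            else:
                new_col = _positive_proba(est, design)
            extra = np.hstack([extra, new_col[:, None]])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.assay_ids_ is None:
            raise ParameterError("model is not fitted")
        X = np.asarray(X, dtype=float)
        col = {a: j for j, a in enumerate(self.assay_ids_)}
        out = np.zeros((X.shape[0], len(self.assay_ids_)))
        extra = np.zeros((X.shape[0], 0))
        for assay in self.spec.order:
            design = np.hstack([X, extra]) if extra.shape[1] else X
            scores = _positive_proba(self.estimators_[assay], design)
            out[:, col[assay]] = scores
            extra = np.hstack([extra, scores[:, None]])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict_proba(X) >= self.threshold, 1, -1).astype(np.int8)


class RandomOrderEnsemble:
    """Chains over several seeded random orders (DRABAL-style score imputation).

    The ensemble's reported performance is the average of the per-order
    metrics, matching the "average of ten random initializations" protocol;
    ``predict_proba`` additionally exposes the across-chain mean score.
    """

    def __init__(self, chains: list[ClassifierChainModel]):
        self.chains = chains

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([c.predict_proba(X) for c in self.chains], axis=0)


def fit_br(dataset: MultiLabelDataset, base: BaseClassifierSpec | None = None,
           threshold: float = 0.5) -> BinaryRelevanceModel:
    """Fit the binary-relevance baseline."""
    return BinaryRelevanceModel(base, threshold).fit(dataset)


def fit_cc(dataset: MultiLabelDataset, spec: ChainSpec,
           threshold: float = 0.5) -> ClassifierChainModel:
    """Fit one classifier chain under ``spec``."""
    return ClassifierChainModel(spec, threshold).fit(dataset)


def sample_orders(assay_ids: Sequence[str], n_orders: int, seed: int) -> list[list[str]]:
    """n distinct seeded permutations of the assay ids (fewer if N! < n)."""
    rng = np.random.default_rng(seed)
    orders: list[list[str]] = []
    seen: set[tuple[str, ...]] = set()
    limit = 1
    for i in range(2, len(assay_ids) + 1):
        limit *= i
    attempts = 0
    while len(orders) < min(n_orders, limit) and attempts < 100 * n_orders:
        perm = [assay_ids[i] for i in rng.permutation(len(assay_ids))]
        key = tuple(perm)
        if key not in seen:
            seen.add(key)
            orders.append(perm)
        attempts += 1
    return orders


def random_order_ensemble(
    dataset: MultiLabelDataset,
    n_orders: int,
    base: BaseClassifierSpec | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> RandomOrderEnsemble:
    """Fit chains over ``n_orders`` distinct random orders with score imputation."""
    if n_orders < 1:
        raise ParameterError("n_orders must be >= 1")
    base = base or BaseClassifierSpec()
    chains = [
        fit_cc(dataset, ChainSpec(order=o, missing_policy="score_impute", base=base),
               threshold)
        for o in sample_orders(dataset.assay_ids, n_orders, seed)
    ]
    return RandomOrderEnsemble(chains)
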