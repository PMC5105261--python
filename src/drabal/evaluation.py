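"""Cross-validated method comparison harness.

Runs k-fold cross-validation (default fivefold: each fold retains ~20% of
compounds for testing only), fits each requested method on the training
portion — for DRABAL the dependency structure is, by default, learned on the
training fold only, so no test label leaks into structure discovery — and
evaluates macro-averaged metrics on the held-out observed labels.  Fold
metrics are averaged, methods are compared with paired t-tests, and the
correctly-predicted-positive overlap (Venn partition averaged over folds) is
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, metrics, model as drabal_model, structure
from .datasets import MultiLabelDataset, make_cv_folds
from .exceptions import ParameterError
from .model import BaseClassifierSpec

logger = logging.getLogger(__name__)

METHODS = ("drabal", "br", "cc_mle", "cc", "random_order")
_HEADLINE = ("sensitivity", "specificity", "precision", "gmean", "f1", "f05")


@dataclass
class MethodSpec:
    """One method entry in a comparison: name + base classifier + options."""

    method: str
    base: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)
    n_orders: int = 10  # random_order only
    chain_order: list[str] | None = None  # cc / cc_mle; default = dataset order
    graph: "structure.LabelDependencyGraph | None" = None  # fixed DAG for drabal

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}")


@dataclass
class ComparisonResult:
    """Averaged metric table, per-fold reports, t-tests and overlap counts."""

    table: pd.DataFrame  # methods x headline metrics (%)
    per_fold: dict[str, list[metrics.MetricReport]]
    ttests: pd.DataFrame  # pairwise per-metric paired t-tests
    overlap: metrics.OverlapCounts | None
    k: int
    seed: int

    def fold_scores(self, method: str, metric: str) -> list[float]:
        return [getattr(r, metric) for r in self.per_fold[method]]

    def summary(self) -> str:
        lines = [self.table.round(2).to_string()]
        if len(self.per_fold) > 1:
            lines.append("")
            lines.append(self.ttests.round(4).to_string(index=False))
        return "\n".join(lines)


def _fit_method(spec: MethodSpec, train: MultiLabelDataset, *, threshold: float,
                structure_alpha: float, seed: int, full: MultiLabelDataset,
                leaky_structure: bool):
    if spec.method == "drabal":
        graph = spec.graph
        if graph is None:
            source = full if leaky_structure else train
            graph = structure.learn_structure(
                source.labels, structure_alpha, assay_ids=source.assay_ids
            )
        return drabal_model.DrabalModel(graph, spec.base, threshold=threshold).fit(train)
    if spec.method == "br":
        return baselines.fit_br(train, spec.base, threshold)
    if spec.method in ("cc", "cc_mle"):
        order = spec.chain_order or list(train.assay_ids)
        policy = "as_negative" if spec.method == "cc_mle" else "score_impute"
        return baselines.fit_cc(
            train, baselines.ChainSpec(order=order, missing_policy=policy,
                                       base=spec.base), threshold)
    return baselines.random_order_ensemble(train, spec.n_orders, spec.base,
                                           seed=seed, threshold=threshold)


def _evaluate_fold(spec: MethodSpec, fitted, test: MultiLabelDataset,
                   threshold: float) -> tuple[metrics.MetricReport, np.ndarray]:
    if spec.method == "random_order":
        # protocol: average the per-order metrics, not the scores
        reports = []
        for chain in fitted.chains:
            pred = chain.predict(test.features)
            reports.append(metrics.evaluate(test.labels, pred))
        mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in _HEADLINE}
        report = metrics.MetricReport(
            **mean, per_assay=reports[0].per_assay, n_assays=reports[0].n_assays
        )
        pred = np.where(fitted.predict_proba(test.features) >= threshold, 1, -1)
        return report, pred.astype(np.int8)
    pred = fitted.predict(test.features)
    return metrics.evaluate(test.labels, pred), pred


def cross_validate(
    dataset: MultiLabelDataset,
    methods: dict[str, MethodSpec],
    k: int = 5,
    seed: int = 0,
    *,
    threshold: float = 0.5,
    structure_alpha: float = 0.05,
    leaky_structure: bool = False,
) -> ComparisonResult:
    """k-fold CV comparison of the requested methods on one dataset."""
    if k < 2:
        raise ParameterError("need k >= 2 folds")
    split = make_cv_folds(dataset.n_compounds, k, seed)
    per_fold: dict[str, list[metrics.MetricReport]] = {m: [] for m in methods}
    fold_overlaps: list[metrics.OverlapCounts] = []

    for f in range(k):
        train_idx, test_idx = split.train_test(f)
        train, test = dataset.subset(train_idx), dataset.subset(test_idx)
        predictions: dict[str, np.ndarray] = {}
        for name, spec in methods.items():
            fitted = _fit_method(spec, train, threshold=threshold,
                                 structure_alpha=structure_alpha, seed=seed,
                                 full=dataset, leaky_structure=leaky_structure)
            report, pred = _evaluate_fold(spec, fitted, test, threshold)
            per_fold[name].append(report)
            predictions[name] = pred
        if len(methods) > 1:
            fold_overlaps.append(metrics.correct_positive_overlap(test.labels,
                                                                  predictions))

    table = pd.DataFrame(
        {m: [float(np.mean([getattr(r, h) for r in per_fold[m]])) for h in _HEADLINE]
         for m in methods},
        index=list(_HEADLINE),
    ).T

    rows = []
    names = list(methods)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for h in _HEADLINE:
                a = [getattr(r, h) for r in per_fold[names[i]]]
                b = [getattr(r, h) for r in per_fold[names[j]]]
                t = metrics.paired_ttest(a, b)
                rows.append({"method_a": names[i], "method_b": names[j], "metric": h,
                             "t": t.statistic, "p": t.p_value,
                             "significant": t.significant})
    ttests = pd.DataFrame(rows, columns=["method_a", "method_b", "metric",
                                         "t", "p", "significant"])

    overlap = None
    if fold_overlaps:
        regions = {key: float(np.mean([o.regions.get(key, 0) for o in fold_overlaps]))
                   for key in fold_overlaps[0].regions}
        overlap = metrics.OverlapCounts(
            regions=regions,
            unique={m: regions[frozenset([m])] for m in methods},
            missed=float(np.mean([o.missed for o in fold_overlaps])),
            total_positives=float(np.mean([o.total_positives for o in fold_overlaps])),
        )
    return ComparisonResult(table=table, per_fold=per_fold, ttests=ttests,
                            overlap=overlap, k=k, seed=seed)
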