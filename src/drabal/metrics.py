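"""Macro-averaged multi-label evaluation and comparison arithmetic.

Per assay j, with A_j^+/A_j^- the indices of observed actual positives and
negatives and Y_j^+/Y_j^- the predicted positives/negatives among those
observed rows:

    sensitivity_j = |A_j^+ ∩ Y_j^+| / |A_j^+|
    specificity_j = |A_j^- ∩ Y_j^-| / |A_j^-|
    precision_j   = |A_j^+ ∩ Y_j^+| / |Y_j^+|

These are macro-averaged over the N assays, and the composite summaries are
computed from the macro averages:

    GMean = sqrt(Sensitivity × Specificity)
    F1    = 2 P S / (P + S)
    F0.5  = 1.25 P S / (0.25 P + S)     (precision weighted twice as much)

Rows whose actual label is missing are excluded from every set; a per-assay
component with an empty denominator contributes 0 to the macro average and is
logged (the zero-convention for degenerate assays).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ACTIVE, INACTIVE, MISSING
from .exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class LabelOutcomeSets:
    """Per-assay index sets of actual/predicted positives and negatives."""

    a_plus: list[np.ndarray]
    a_minus: list[np.ndarray]
    y_plus: list[np.ndarray]
    y_minus: list[np.ndarray]


@dataclass
class MetricReport:
    """Headline macro-averaged percentages plus the per-assay breakdown."""

    sensitivity: float
    specificity: float
    precision: float
    gmean: float
    f1: float
    f05: float
    per_assay: pd.DataFrame
    n_assays: int

    def as_dict(self, ndigits: int = 2) -> dict[str, float]:
        return {
            k: round(getattr(self, k), ndigits)
            for k in ("sensitivity", "specificity", "precision", "gmean", "f1", "f05")
        }

    def to_json(self, path) -> None:
        import json
        payload = {"headline": self.as_dict(),
                   "per_assay": self.per_assay.to_dict(orient="records"),
                   "n_assays": self.n_assays}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = ", ".join(f"{k}={v:.2f}%" for k, v in self.as_dict().items())
        return f"MetricReport({head}; N={self.n_assays})"


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    significant: bool


def _check_shapes(actual: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape or actual.ndim != 2:
        raise ParameterError(f"shape mismatch: {actual.shape} vs {predicted.shape}")
    return actual, predicted


def outcome_sets(actual: np.ndarray, predicted: np.ndarray) -> LabelOutcomeSets:
    """Per-assay A+/A-/Y+/Y- index sets over rows with an observed actual label."""
    actual, predicted = _check_shapes(actual, predicted)
    a_plus, a_minus, y_plus, y_minus = [], [], [], []
    for j in range(actual.shape[1]):
        obs = actual[:, j] != MISSING
        a_plus.append(np.flatnonzero(obs & (actual[:, j] == ACTIVE)))
        a_minus.append(np.flatnonzero(obs & (actual[:, j] == INACTIVE)))
        y_plus.append(np.flatnonzero(obs & (predicted[:, j] == ACTIVE)))
        y_minus.append(np.flatnonzero(obs & (predicted[:, j] != ACTIVE)))
    return LabelOutcomeSets(a_plus, a_minus, y_plus, y_minus)


def evaluate(actual: np.ndarray, predicted: np.ndarray) -> MetricReport:
    """Macro-averaged sensitivity/specificity/precision/GMean/F1/F0.5 (in %)."""
    actual, predicted = _check_shapes(actual, predicted)
    N = actual.shape[1]
    rows = []
    for j in range(N):
        obs = actual[:, j] != MISSING
        act = actual[obs, j] == ACTIVE
        pred = predicted[obs, j] == ACTIVE
        tp = int(np.sum(act & pred))
        fn = int(np.sum(act & ~pred))
        tn = int(np.sum(~act & ~pred))
        fp = int(np.sum(~act & pred))
        n_pos, n_neg, n_pred_pos = tp + fn, tn + fp, tp + fp
        for name, denom in (("A+", n_pos), ("A-", n_neg), ("Y+", n_pred_pos)):
            if denom == 0:
                logger.info("assay column %d: empty %s denominator -> contributes 0", j, name)
        rows.append({
            "assay": j,
            "sensitivity": tp / n_pos if n_pos else 0.0,
            "specificity": tn / n_neg if n_neg else 0.0,
            "precision": tp / n_pred_pos if n_pred_pos else 0.0,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        })
    per_assay = pd.DataFrame(rows)
    sens = 100.0 * per_assay["sensitivity"].mean()
    spec = 100.0 * per_assay["specificity"].mean()
    prec = 100.0 * per_assay["precision"].mean()
    gmean = math.sqrt(sens * spec)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    f05 = 1.25 * prec * sens / (0.25 * prec + sens) if 0.25 * prec + sens > 0 else 0.0
    return MetricReport(sensitivity=sens, specificity=spec, precision=prec,
                        gmean=gmean, f1=f1, f05=f05, per_assay=per_assay, n_assays=N)


def relative_improvement(score_a: float, score_b: float) -> float:
    """Percent gain of a over b: 100 (a - b) / b, rounded to 2 decimals."""
    if score_b <= 0:
        raise ParameterError("reference score must be positive")
    return round(100.0 * (score_a - score_b) / score_b, 2)


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float],
                 alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test on fold-wise metric differences.

    A zero-variance difference vector is degenerate for the t statistic and
    is reported as not significant with p = 1 (and logged).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("score lists must share a length >= 2")
    diffs = a - b
    if np.ptp(diffs) == 0.0:
        logger.info("paired_ttest: zero-variance differences -> degenerate, p = 1")
        return TTestResult(statistic=0.0, p_value=1.0, significant=False)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(t), p_value=float(p),
                       significant=bool(p <= alpha))


@dataclass
class OverlapCounts:
    """Venn partition of correctly predicted actual positives across methods."""

    regions: dict[frozenset, int]  # exactly-this-subset-of-methods counts
    unique: dict[str, int]
    missed: int
    total_positives: int


def correct_positive_overlap(actual: np.ndarray,
                             predictions: Mapping[str, np.ndarray]) -> OverlapCounts:
    """Count, per Venn region over methods, the (row, assay) actual positives
    each exact subset of methods predicts correctly."""
    if not predictions:
        raise ParameterError("at least one method is required")
    actual = np.asarray(actual)
    names = sorted(predictions)
    universe = actual == ACTIVE
    total = int(universe.sum())
    hit_bits = np.zeros(actual.shape, dtype=np.int64)
    for k, name in enumerate(names):
        pred = np.asarray(predictions[name])
        if pred.shape != actual.shape:
            raise ParameterError(f"prediction {name!r} has shape {pred.shape}")
        hit_bits |= ((pred == ACTIVE) & universe).astype(np.int64) << k
    patterns = hit_bits[universe]
    counts = np.bincount(patterns, minlength=1 << len(names))
    regions: dict[frozenset, int] = {}
    for pattern in range(1, 1 << len(names)):
        members = frozenset(n for k, n in enumerate(names) if pattern >> k & 1)
        regions[members] = int(counts[pattern])
    unique = {
        name: regions[frozenset([name])]
        for name in names
    }
    return OverlapCounts(regions=regions, unique=unique,
                         missed=int(counts[0]), total_positives=total)
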