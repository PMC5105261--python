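"""Data model and I/O for multi-assay activity data.

High-throughput screening (HTS) assays report, per compound, an active (+1) or
inactive (-1) outcome against one biological target.  Integrating several
assays over a shared compound library yields a multi-label dataset in which a
compound untested in a given assay carries the missing-label code 0.  This
module provides the per-assay record sets, their integration with a compound
feature table, summary arithmetic (class sizes, imbalance ratios, interaction
totals) and seeded cross-validation splitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    DataFormatError,
    EmptyDatasetError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Outcome vocabulary: only these strings (case-insensitive) map to labels;
#: everything else (Inconclusive, Unspecified, Probe, ...) is dropped.
DEFAULT_OUTCOME_MAP = {"active": 1, "inactive": -1}

ACTIVE, INACTIVE, MISSING = 1, -1, 0


@dataclass
class AssayRecordSet:
    """Outcomes of a single assay: compound id -> +1 (active) / -1 (inactive)."""

    assay_id: str
    records: dict[str, int]
    target_name: str | None = None

    def __post_init__(self) -> None:
        bad = {c: o for c, o in self.records.items() if o not in (ACTIVE, INACTIVE)}
        if bad:
            raise DataError(f"assay {self.assay_id!r}: outcomes must be +1/-1, got {bad}")

    @property
    def n_active(self) -> int:
        return sum(1 for o in self.records.values() if o == ACTIVE)

    @property
    def n_inactive(self) -> int:
        return sum(1 for o in self.records.values() if o == INACTIVE)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MultiLabelDataset:
    """An M x d feature matrix aligned with an M x N label matrix over {+1,-1,0}.

    Rows of ``features`` and ``labels`` are keyed by ``compound_ids`` in the
    same order; label columns follow ``assay_ids``.
    """

    compound_ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    assay_ids: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        M = len(self.compound_ids)
        if self.features.ndim != 2 or self.features.shape[0] != M:
            raise ParameterError("features must be an M x d matrix aligned with compound_ids")
        if self.labels.shape != (M, len(self.assay_ids)):
            raise ParameterError("labels must be an M x N matrix aligned with assay_ids")
        if not np.isin(self.labels, (ACTIVE, INACTIVE, MISSING)).all():
            raise DataError("label entries must be in {+1, -1, 0}")
        if len(set(self.compound_ids)) != M:
            raise DataError("duplicate compound_ids")
        if M and (self.labels == MISSING).all(axis=1).any():
            raise DataError("every compound must have at least one non-missing label")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def missing_fraction(self) -> float:
        return float((self.labels == MISSING).mean()) if self.labels.size else 0.0

    def subset(self, indices: Sequence[int]) -> "MultiLabelDataset":
        """Row subset (used by cross-validation folds)."""
        idx = np.asarray(indices, dtype=int)
        return MultiLabelDataset(
            compound_ids=[self.compound_ids[i] for i in idx],
            features=self.features[idx],
            labels=self.labels[idx],
            assay_ids=list(self.assay_ids),
            feature_names=self.feature_names,
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, labels_path: str | Path, features_path: str | Path) -> None:
        """Write the label and feature tables in the package TSV dialect."""
        lab = pd.DataFrame(self.labels, columns=self.assay_ids)
        lab.insert(0, "compound_id", self.compound_ids)
        lab.to_csv(labels_path, sep="\t", index=False)
        names = self.feature_names or [f"f{j}" for j in range(self.n_features)]
        feat = pd.DataFrame(self.features, columns=names)
        feat.insert(0, "compound_id", self.compound_ids)
        feat.to_csv(features_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, labels_path: str | Path, features_path: str | Path) -> "MultiLabelDataset":
        lab = pd.read_csv(labels_path, sep="\t", dtype={"compound_id": str})
        feat = pd.read_csv(features_path, sep="\t", dtype={"compound_id": str})
        for name, df in (("labels", lab), ("features", feat)):
            if "compound_id" not in df.columns:
                raise DataFormatError(f"{name} table lacks a compound_id column")
        feat = feat.set_index("compound_id").loc[lab["compound_id"]]
        return cls(
            compound_ids=lab["compound_id"].tolist(),
            features=feat.to_numpy(dtype=float),
            labels=lab.drop(columns="compound_id").to_numpy(),
            assay_ids=[c for c in lab.columns if c != "compound_id"],
            feature_names=list(feat.columns),
        )


@dataclass
class DatasetSummary:
    """Per-assay class sizes plus the total interaction count."""

    per_assay: pd.DataFrame  # columns: assay_id, n_active, n_inactive, fold, active_pct
    total_interactions: int

    @classmethod
    def from_counts(
        cls, assay_ids: Sequence[str], actives: Sequence[int], inactives: Sequence[int]
    ) -> "DatasetSummary":
        rows = []
        for a_id, na, ni in zip(assay_ids, actives, inactives, strict=True):
            if na + ni > 0:
                pct, fold = imbalance_ratio(na, ni)
            else:
                pct, fold = 0.0, None
            rows.append(
                {"assay_id": a_id, "n_active": int(na), "n_inactive": int(ni),
                 "fold": fold, "active_pct": pct}
            )
        total = int(sum(actives) + sum(inactives))
        return cls(per_assay=pd.DataFrame(rows), total_interactions=total)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [self.per_assay.to_string(index=False)]
        lines.append(f"Total interactions: {self.total_interactions:,}")
        return "\n".join(lines)


@dataclass
class CVSplit:
    """k mutually disjoint, near-equal-size row index folds."""

    k: int
    folds: list[np.ndarray]
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[fold]
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train), np.sort(test)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def read_assay_table(
    path: str | Path,
    assay_id: str,
    *,
    compound_col: str = "compound_id",
    outcome_col: str = "outcome",
    delimiter: str = "\t",
    outcome_map: Mapping[str, int] | None = None,
    target_name: str | None = None,
) -> AssayRecordSet:
    """Read one assay's activity table (PubChem-BioAssay-style export).

    Outcome strings are matched case-insensitively against ``outcome_map``
    (default Active -> +1, Inactive -> -1); rows with any other outcome are
    dropped with a logged count.  Duplicate compounds with conflicting
    outcomes raise :class:`DataError`.
    """
    omap = {k.lower(): v for k, v in (outcome_map or DEFAULT_OUTCOME_MAP).items()}
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing_cols = {compound_col, outcome_col} - set(df.columns)
    if missing_cols:
        raise DataFormatError(f"{path}: missing required column(s) {sorted(missing_cols)}")
    records: dict[str, int] = {}
    dropped = 0
    for cid, outcome in zip(df[compound_col], df[outcome_col]):
        label = omap.get(str(outcome).strip().lower())
        if label is None:
            dropped += 1
            continue
        if cid in records and records[cid] != label:
            raise DataError(
                f"assay {assay_id!r}: compound {cid!r} has conflicting outcomes"
            )
        records[str(cid)] = label
    if dropped:
        logger.info("assay %s: dropped %d row(s) with unmapped outcomes", assay_id, dropped)
    return AssayRecordSet(assay_id=assay_id, records=records, target_name=target_name)


def merge_assays(
    assays: Sequence[AssayRecordSet],
    features: Mapping[str, np.ndarray] | pd.DataFrame,
) -> MultiLabelDataset:
    """Integrate per-assay record sets into one multi-label dataset.

    Label entry (i, j) is compound i's outcome in assay j, or 0 when untested.
    Compounds absent from the feature table are dropped with a logged count
    (mirroring exclusion of compounds that fail feature generation).
    """
    if not assays:
        raise ParameterError("at least one assay is required")
    if isinstance(features, pd.DataFrame):
        feat_map: Mapping[str, np.ndarray] = {
            str(cid): row.to_numpy(dtype=float) for cid, row in features.iterrows()
        }
        feature_names = list(features.columns)
    else:
        feat_map = features
        feature_names = None

    # compound order: first appearance across assays (deterministic)
    order: list[str] = []
    seen: set[str] = set()
    for assay in assays:
        for cid in assay.records:
            if cid not in seen:
                seen.add(cid)
                order.append(cid)
    kept = [cid for cid in order if cid in feat_map]
    n_dropped = len(order) - len(kept)
    if n_dropped:
        logger.info("merge_assays: dropped %d compound(s) without features", n_dropped)
    if not kept:
        raise EmptyDatasetError("no compounds with features survive the merge")

    X = np.vstack([np.asarray(feat_map[cid], dtype=float) for cid in kept])
    labels = np.zeros((len(kept), len(assays)), dtype=np.int8)
    pos = {cid: i for i, cid in enumerate(kept)}
    for j, assay in enumerate(assays):
        for cid, outcome in assay.records.items():
            if cid in pos:
                labels[pos[cid], j] = outcome
    return MultiLabelDataset(
        compound_ids=kept,
        features=X,
        labels=labels,
        assay_ids=[a.assay_id for a in assays],
        feature_names=feature_names,
    )


def imbalance_ratio(n_active: int, n_inactive: int) -> tuple[float, int | None]:
    """Class-imbalance arithmetic in the two conventions of HTS reporting.

    Returns ``(percent_form, fold_form)`` where ``percent_form`` is
    100 * actives / total interactions truncated at two decimals (the
    convention under which 77 actives out of 424,929 interactions prints as
    0.01%), and ``fold_form`` is round(inactives / actives), i.e. the ``k`` of
    a "1:k" active-to-inactive ratio (None when there are no actives).
    """
    if n_active < 0 or n_inactive < 0:
        raise ParameterError("counts must be non-negative")
    total = n_active + n_inactive
    if total == 0:
        raise ParameterError("at least one count must be positive")
    percent = math.floor(100.0 * n_active / total * 100 + 1e-9) / 100
    fold = round(n_inactive / n_active) if n_active else None
    return percent, fold


def dataset_summary(dataset: MultiLabelDataset) -> DatasetSummary:
    """Per-assay active/inactive counts over non-missing entries, plus totals."""
    actives = (dataset.labels == ACTIVE).sum(axis=0)
    inactives = (dataset.labels == INACTIVE).sum(axis=0)
    return DatasetSummary.from_counts(dataset.assay_ids, actives.tolist(), inactives.tolist())


def make_cv_folds(M: int, k: int, seed: int) -> CVSplit:
    """Seeded unstratified k-fold split of row indices; fold sizes differ by <= 1."""
    if not 2 <= k <= M:
        raise ParameterError(f"need 2 <= k <= M, got k={k}, M={M}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    return CVSplit(k=k, folds=folds, seed=seed)
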