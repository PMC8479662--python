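"""Readers and writers for feature matrices, survival tables, folds, scores and metrics.

All tabular formats are plain delimited text (tab preferred, comma accepted)
so that inputs and outputs are versionable and diffable.  Missing values are
encoded by the single case-sensitive token ``NA``.  Joins between tables are
always by patient id, never by row position.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

MISSING_TOKEN = "NA"

__all__ = [
    "FeatureMatrix",
    "SurvivalRecord",
    "FoldAssignment",
    "read_feature_table",
    "write_feature_table",
    "read_survival_table",
    "write_survival_table",
    "make_folds",
    "write_scores",
    "read_scores",
    "write_metrics",
    "read_metrics",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class FeatureMatrix:
    """A samples x features value grid for one modality.

    ``values`` is a float array of shape ``(len(sample_ids), len(feature_ids))``;
    missing entries are ``NaN``.  ``modality`` tags the matrix as ``"genomic"``
    or ``"image"`` (free-form tags are tolerated but discouraged).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: str = "genomic"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.feature_ids)})"
            )
        if np.isinf(self.values).any():
            raise ValidationError("non-finite (infinite) value in feature matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Rows restricted to ``ids``, in the given order (join by id)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[str(s)] for s in ids]
        return FeatureMatrix(list(ids), list(self.feature_ids), self.values[rows], self.modality)

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [index[str(f)] for f in ids]
        return FeatureMatrix(list(self.sample_ids), list(ids), self.values[:, cols], self.modality)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event indicator, 5-year class label.

    ``label`` is 1 for shorter-term survivors (death within the horizon; poor
    prognosis) and 0 for longer-term survivors; ``None`` when not yet derived.
    """

    patient_id: str
    time: float
    event: int
    label: int | None = None

    def __post_init__(self) -> None:
        self.patient_id = str(self.patient_id)
        self.time = float(self.time)
        self.event = int(self.event)
        if not (self.time > 0):
            raise ValidationError(f"patient {self.patient_id}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"patient {self.patient_id}: event must be 0/1, got {self.event}")
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise ValidationError(
                    f"patient {self.patient_id}: label must be 0/1, got {self.label}"
                )


@dataclass
class FoldAssignment:
    """A k-fold partition of the cohort, mapping patient id -> fold index."""

    k: int
    assignment: dict[str, int] = field(default_factory=dict)

    def fold_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]

    def __post_init__(self) -> None:
        for p, f in self.assignment.items():
            if not (0 <= f < self.k):
                raise ValidationError(f"fold index {f} for patient {p} outside [0, {self.k})")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_feature_table(path: str | Path, modality: str = "genomic") -> FeatureMatrix:
    """Read a delimited feature table: header row of feature ids, first column sample ids.

    The token ``NA`` marks missing values.  Any other non-numeric cell is a
    parse error reported with its row and column.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):  # pandas would mangle these silently
        raise ValidationError(f"{path}: duplicate feature id: {_first_duplicate(header)!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    values = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if cell == MISSING_TOKEN:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell {cell!r} at sample "
                        f"{df.index[i]!r}, feature {df.columns[j]!r}"
                    ) from None
    return FeatureMatrix(
        [str(s) for s in df.index], [str(f) for f in df.columns], values, modality
    )


def write_feature_table(m: FeatureMatrix, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id" + sep + sep.join(m.feature_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            cells = [
                MISSING_TOKEN if math.isnan(v) else repr(float(v)) for v in m.values[i]
            ]
            fh.write(sid + sep + sep.join(cells) + "\n")


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival table with columns patient_id, time, event[, label]."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    has_label = "label" in df.columns
    records = []
    for _, row in df.iterrows():
        label = None
        if has_label and not pd.isna(row["label"]):
            label = int(row["label"])
        records.append(
            SurvivalRecord(str(row["patient_id"]), float(row["time"]), int(row["event"]), label)
        )
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate patient id {_first_duplicate(ids)!r}")
    return records


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["patient_id", "time", "event", "label"]) + "\n")
        for r in records:
            label = MISSING_TOKEN if r.label is None else str(r.label)
            fh.write(sep.join([r.patient_id, repr(float(r.time)), str(r.event), label]) + "\n")


def make_folds(
    records: Sequence[SurvivalRecord],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Partition the cohort into k folds (80/20 train/test splits for k=5).

    Stratifies on the binary 5-year label by default so that no fold is
    degenerate; ``stratified=False`` gives the plain shuffled partition.
    Deterministic for a given seed.
    """
    n = len(records)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    ids = np.array([r.patient_id for r in records])
    if stratified:
        labels = [r.label for r in records]
        if any(l is None for l in labels):
            raise ValidationError("stratified folds require derived labels on every record")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), np.array(labels, dtype=int))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splits):
        for i in test_idx:
            assignment[str(ids[i])] = fold
    return FoldAssignment(k=k, assignment=assignment)


def write_scores(
    patient_ids: Sequence[str],
    folds: Sequence[int],
    scores: Sequence[float],
    labels: Sequence[int],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write per-patient prediction scores as delimited text (full precision)."""
    if len(patient_ids) == 0:
        raise ValueError("empty score set: nothing to write")
    if not (len(patient_ids) == len(folds) == len(scores) == len(labels)):
        raise ValueError("score columns must be aligned")
    with open(path, "w") as fh:
        fh.write(sep.join(["patient_id", "fold", "score", "label"]) + "\n")
        for pid, f, s, y in zip(patient_ids, folds, scores, labels):
            fh.write(sep.join([str(pid), str(int(f)), repr(float(s)), str(int(y))]) + "\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    return df


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_metrics(report: Mapping, path: str | Path) -> None:
    """Write a metrics report as JSON; undefined (NaN) metrics become null."""
    if not report:
        raise ValueError("empty metrics report: nothing to write")
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
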