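"""Tabular dataset I/O, run configuration and stratified fold construction.

The :class:`Dataset` container is the currency passed between every stage of
the pipeline: a numeric feature matrix, a binary label vector ({0, 1} at the
boundary; the boosting engine maps to {-1, +1} internally), feature names,
sample identifiers and an optional cohort-window tag per sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ssmboost")

VALID_COHORT_WINDOWS = (7, 14, 28)


@dataclass
class Dataset:
    """Feature matrix plus binary labels and per-sample metadata.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Numeric features; must be finite.
    y : ndarray of shape (n_samples,)
        Binary labels, 1 = positive (event, e.g. sepsis), 0 = negative.
    feature_names : list of str
        Unique column names, one per feature, order preserved.
    sample_ids : list of str, optional
        Defaults to ``"s0" .. "s{n-1}"``.
    cohort : ndarray or None
        Optional per-sample cohort-window tag in {7, 14, 28}.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] | None = None
    cohort: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        n, d = self.X.shape
        if n < 1:
            raise ValueError("Dataset must contain at least one sample")
        if d != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        bad_labels = set(np.unique(self.y)) - {0, 1}
        if bad_labels:
            raise ValueError(
                f"labels must be binary {{0,1}}; found value(s) {sorted(bad_labels)}"
            )
        self.y = self.y.astype(int)
        if len(self.y) != n:
            raise ValueError("y length does not match X")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match X")
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort)
            if len(self.cohort) != n:
                raise ValueError("cohort length does not match X")
            bad = set(np.unique(self.cohort)) - set(VALID_COHORT_WINDOWS)
            if bad:
                raise ValueError(f"cohort values must be in {VALID_COHORT_WINDOWS}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row subset preserving metadata alignment."""
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            cohort=None if self.cohort is None else self.cohort[idx],
        )


@dataclass
class RunConfig:
    """Configuration for an end-to-end run (simulate → tune → train → explain)."""

    mode: str = "bayes"  # fixed ensemble mode or "bayes" for tuned selection
    rounds: int = 5
    smote: bool = True
    smote_k: int = 8
    k_cv: int = 10
    seed: int = 0
    windows: tuple[int, ...] = (7,)
    n_samples: int = 912
    n_features: int = 49
    prevalence: float = 0.41
    tune_budget: int = 8
    metrics: tuple[str, ...] = ("auc", "accuracy", "precision", "recall", "f1")
    out_dir: str = "ssmboost_out"
    learner_space: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.k_cv < 2:
            raise ValueError("k_cv must be >= 2")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        for name, (lo, hi) in (self.learner_space or {}).items():
            if not lo < hi:
                raise ValueError(f"space bound for {name!r} must have low < high")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or YAML; unknown keys warn instead of failing."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in raw.items() if k in known}
        for tup_key in ("windows", "metrics"):
            if tup_key in kwargs:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        d["metrics"] = list(self.metrics)
        return d


def read_table(path: str | Path, label_column: str = "label") -> Dataset:
    """Read a CSV file into a :class:`Dataset`.

    All columns other than ``label_column``, an optional ``cohort`` column and
    an optional ``sample_id`` column are treated as numeric features. Parse
    failures report the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    sample_ids = None
    if "sample_id" in df.columns:
        sample_ids = df.pop("sample_id").astype(str).tolist()
    cohort = None
    if "cohort" in df.columns:
        cohort = df.pop("cohort").to_numpy()
    y_raw = df.pop(label_column)
    bad = set(pd.unique(y_raw)) - {0, 1}
    if bad:
        raise ValueError(
            f"label column {label_column!r} contains non-binary value(s) "
            f"{sorted(bad)}"
        )
    feature_names = [str(c) for c in df.columns]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError(
            "missing values present; impute or drop before loading "
            "(see impute_median)"
        )
    return Dataset(
        X=df.to_numpy(dtype=float),
        y=y_raw.to_numpy(),
        feature_names=feature_names,
        sample_ids=sample_ids,
        cohort=cohort,
    )


def write_table(dataset: Dataset, path: str | Path, label_column: str = "label") -> None:
    """Write a Dataset as CSV: features, label column, optional cohort column."""
    if dataset.n_features == 0:
        raise ValueError("cannot write a dataset with no features")
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df[label_column] = dataset.y
    if dataset.cohort is not None:
        df["cohort"] = dataset.cohort
    df.insert(0, "sample_id", dataset.sample_ids)
    # %.17g keeps binary64 values exact across the round trip
    df.to_csv(path, index=False, float_format="%.17g")


def impute_median(df: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing numeric cells (optional pre-load cleaning)."""
    return df.fillna(df.median(numeric_only=True))


@dataclass
class FoldAssignment:
    """Per-sample fold index in ``0 .. k_cv - 1``."""

    fold_index: np.ndarray
    k_cv: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_idx, val_idx) for one fold."""
        val = np.flatnonzero(self.fold_index == fold)
        train = np.flatnonzero(self.fold_index != fold)
        return train, val


def stratified_folds(y: np.ndarray, k_cv: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment by within-class round-robin dealing.

    Members of each class are shuffled with the seed then dealt to folds
    0, 1, ..., k_cv-1 cyclically, so every fold's class counts differ from
    exact proportionality by at most one sample.
    """
    y = np.asarray(y)
    if k_cv < 2:
        raise ValueError("k_cv must be >= 2")
    rng = np.random.default_rng(seed)
    fold_index = np.full(len(y), -1, dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < k_cv:
            raise ValueError(
                f"class {cls} has only {len(members)} members; "
                f"use k_cv <= {len(members)}"
            )
        members = rng.permutation(members)
        fold_index[members] = np.arange(len(members)) % k_cv
    return FoldAssignment(fold_index=fold_index, k_cv=k_cv)
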