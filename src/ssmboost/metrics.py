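"""Confusion-matrix metrics, rank-based AUC, and stratified k-fold evaluation.

The harness fits inside each training fold only: features are standardized on
the fold's training rows, SMOTE (when enabled) augments the training rows
only, and the validation fold keeps its original class distribution. Fold
scores are summarized as mean +/- sample SD (ddof = 1) across folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import clone

from .io import Dataset, stratified_folds
from .smote import SMOTE

METRIC_NAMES = ("auc", "accuracy", "precision", "recall", "f1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y: np.ndarray, yhat: np.ndarray) -> ConfusionCounts:
    """Confusion counts for {0,1} labels and predictions."""
    y = np.asarray(y).astype(int)
    yhat = np.asarray(yhat).astype(int)
    if len(y) != len(yhat):
        raise ValueError("y and yhat must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def recall(c: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN)."""
    return _safe_div(c.tp, c.tp + c.fn, "recall")


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP / (TP + FP)."""
    return _safe_div(c.tp, c.tp + c.fp, "precision")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall."""
    p, r = precision(c), recall(c)
    return _safe_div(2 * p * r, p + r, "f1")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / n."""
    return _safe_div(c.tp + c.tn, c.n, "accuracy")


def auc_roc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic with ties counted one half.

    Equals the probability a uniformly drawn positive outranks a uniformly
    drawn negative; invariant under strictly monotone score transforms.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def score_metrics(y: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """All five metrics from continuous scores; hard labels at prob 0.5."""
    prob = expit(scores) if (scores.min() < 0 or scores.max() > 1) else scores
    yhat = (prob >= threshold).astype(int)
    c = confusion(y, yhat)
    return {
        "auc": auc_roc(y, scores),
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1(c),
    }


@dataclass
class MetricReport:
    """Per-fold metric values with mean +/- sample SD summaries."""

    per_fold: dict[str, list[float]]
    k_cv: int
    sd_convention: str = "sample SD across folds (ddof=1)"
    extra: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean(self.per_fold[name]))

    def sd(self, name: str) -> float:
        vals = self.per_fold[name]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in self.per_fold}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k_cv": self.k_cv,
            "sd_convention": self.sd_convention,
            "per_fold": self.per_fold,
            "summary": {
                m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self.per_fold
            },
            **self.extra,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table_row(self, model_name: str) -> pd.DataFrame:
        """One row of a results table with "mean ± sd" strings."""
        row = {
            m: f"{self.mean(m):.3f} ± {self.sd(m):.3f}" for m in self.per_fold
        }
        return pd.DataFrame([row], index=[model_name])


def cross_validate(
    model,
    data: Dataset,
    k_cv: int = 10,
    seed: int = 0,
    smote: SMOTE | None = None,
) -> MetricReport:
    """Stratified k-fold evaluation of an unfitted classifier.

    ``model`` is cloned per fold. Standardization statistics come from the
    training rows of each fold; SMOTE, when given, augments training rows
    only — validation folds always keep the original distribution (no
    synthetic row can reach a validation fold by construction, and the flags
    returned by the sampler are asserted against the validation indices).
    """
    folds = stratified_folds(data.y, k_cv=k_cv, seed=seed)
    per_fold: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for fold in range(k_cv):
        train_idx, val_idx = folds.split(fold)
        X_tr, y_tr = data.X[train_idx], data.y[train_idx]
        X_va, y_va = data.X[val_idx], data.y[val_idx]
        mu = X_tr.mean(axis=0)
        sd = np.maximum(X_tr.std(axis=0), 1e-12)
        X_tr = (X_tr - mu) / sd
        X_va = (X_va - mu) / sd
        n_original = len(y_tr)
        if smote is not None:
            X_tr, y_tr, flags = smote.fit_resample(X_tr, y_tr)
            assert not flags[:n_original].any(), "originals must stay unflagged"
        est = clone(model)
        try:
            est.fit(X_tr, y_tr)
        except TypeError:
            est.fit(X_tr, y_tr, sample_weight=None)
        if hasattr(est, "decision_function"):
            scores = np.asarray(est.decision_function(X_va), dtype=float)
        else:
            scores = np.clip(est.predict_proba(X_va)[:, 1], 1e-12, 1 - 1e-12)
            scores = np.log(scores / (1 - scores))
        fold_metrics = score_metrics(y_va, scores)
        for m in METRIC_NAMES:
            per_fold[m].append(fold_metrics[m])
    return MetricReport(per_fold=per_fold, k_cv=k_cv)
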