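"""Synthetic minority oversampling (SMOTE) to class parity.

For each minority instance x_i the k nearest other minority points are found
by Euclidean distance (k = 8 by default); a synthetic sample is placed
uniformly at random on the segment to one of them:
``x_new = x_i + lambda (x_nn - x_i)``, ``lambda ~ U(0, 1)``. Generation
cycles through minority points in index order until the minority count
matches the majority count. SMOTE belongs inside training folds only —
oversampling before splitting leaks synthetic copies of validation points
into training; the cross-validation harness enforces this and synthetic rows
are flagged so leakage is checkable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import Dataset

logger = logging.getLogger("ssmboost")


@dataclass
class SmoteConfig:
    k: int = 8
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def minority_neighbors(X_min: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority point's k nearest other minority points.

    Ties break toward the lower index. If fewer than k other points exist,
    k is reduced (and logged).
    """
    X_min = np.asarray(X_min, dtype=float)
    m = len(X_min)
    if m < 2:
        raise ValueError("need at least 2 minority samples")
    if k > m - 1:
        logger.warning("k=%d exceeds minority size - 1; reduced to %d", k, m - 1)
        k = m - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    dist, idx = nn.kneighbors(X_min)
    out = np.empty((m, k), dtype=int)
    for i in range(m):
        d, j = dist[i], idx[i]
        # stable resort: distance first, index second, then drop self
        order = np.lexsort((j, d))
        neigh = [jj for jj in j[order] if jj != i][:k]
        out[i] = neigh
    return out


def interpolate(x_i: np.ndarray, x_nn: np.ndarray, lam: float) -> np.ndarray:
    """Point at fraction ``lam`` along the segment from x_i to x_nn."""
    x_i = np.asarray(x_i, dtype=float)
    x_nn = np.asarray(x_nn, dtype=float)
    if x_i.shape != x_nn.shape:
        raise ValueError("endpoint dimension mismatch")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    return x_i + lam * (x_nn - x_i)


class SMOTE:
    """SMOTE oversampler with an imbalanced-learn-style ``fit_resample``.

    Parameters
    ----------
    k_neighbors : int, default 8
        Neighborhood size for parent selection.
    target_ratio : float, default 1.0
        Desired minority/majority count ratio after resampling (1.0 = parity).
    random_state : int, default 0

    Notes
    -----
    Neighbor search runs on features standardized to the input sample's own
    mean/SD so no single large-scale feature dominates the metric; synthetic
    points themselves are interpolated in the original feature space.
    """

    def __init__(self, k_neighbors: int = 8, target_ratio: float = 1.0,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.random_state = random_state

    def fit_resample(self, X, y):
        """Return (X_out, y_out, synthetic_flag); originals come first, verbatim."""
        SmoteConfig(k=self.k_neighbors, target_ratio=self.target_ratio,
                    seed=self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("both classes must be present for SMOTE")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        n_new = int(round(self.target_ratio * n_maj)) - n_min
        flags = np.zeros(len(y), dtype=bool)
        if n_new <= 0:
            return X.copy(), y.copy(), flags

        min_idx = np.flatnonzero(y == minority)
        X_min = X[min_idx]
        mu = X_min.mean(axis=0)
        sd = np.maximum(X_min.std(axis=0), 1e-12)
        neighbors = minority_neighbors((X_min - mu) / sd, self.k_neighbors)

        rng = np.random.default_rng(self.random_state)
        new_rows = np.empty((n_new, X.shape[1]))
        for t in range(n_new):
            i = t % len(X_min)  # cycle through minority points in index order
            nn = neighbors[i][rng.integers(0, neighbors.shape[1])]
            lam = rng.random()
            new_rows[t] = interpolate(X_min[i], X_min[nn], lam)
        X_out = np.vstack([X, new_rows])
        y_out = np.concatenate([y, np.full(n_new, minority)])
        flag_out = np.concatenate([flags, np.ones(n_new, dtype=bool)])
        return X_out, y_out, flag_out


def balance(data: Dataset, config: SmoteConfig | None = None) -> tuple[Dataset, np.ndarray]:
    """Oversample a training-fold Dataset to class parity.

    Returns the augmented Dataset and a boolean flag marking synthetic rows.
    The caller is responsible for passing a *training* fold only.
    """
    config = config or SmoteConfig()
    sampler = SMOTE(k_neighbors=config.k, target_ratio=config.target_ratio,
                    random_state=config.seed)
    X_out, y_out, flags = sampler.fit_resample(data.X, data.y)
    n_new = int(flags.sum())
    ids = list(data.sample_ids) + [f"synthetic_{i}" for i in range(n_new)]
    cohort = None
    if data.cohort is not None:
        cohort = np.concatenate([data.cohort, np.full(n_new, data.cohort[0])])
    out = Dataset(X=X_out, y=y_out, feature_names=list(data.feature_names),
                  sample_ids=ids, cohort=cohort)
    return out, flags
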