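"""Model-agnostic Shapley-value attribution and explanation tables.

Attributions are computed on the ensemble's continuous score, not hard
labels: positive phi pushes the predicted risk up, negative pushes it down.
The value of a coalition S is the model's expected score when features in S
take the explained sample's values and the rest are filled from background
rows. Two estimators share that value function:

* exact subset enumeration (d <= 12) — all 2^d coalitions, Shapley weights
  s!(d-1-s)!/d!; satisfies efficiency, symmetry and dummy exactly;
* kernel weighted-least-squares (larger d) — complete coalition-size groups
  are enumerated while the budget allows, remaining coalitions are sampled,
  and the WLS solve is constrained so base + sum(phi) equals the model score
  (efficiency holds by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd


@dataclass
class Explanation:
    """Per-sample, per-feature Shapley values on the model-score scale."""

    phi: np.ndarray  # (n, d)
    base_value: float
    X: np.ndarray  # (n, d) feature values aligned with phi
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.phi.shape != self.X.shape:
            raise ValueError("phi and X must be aligned")

    @property
    def n_samples(self) -> int:
        return self.phi.shape[0]

    @property
    def n_features(self) -> int:
        return self.phi.shape[1]


def _coalition_values(model_fn, X, background, masks, batch_rows=200_000):
    """v(x, S) for every sample and mask: mean model score over background
    rows with the masked features replaced by the sample's values."""
    n, d = X.shape
    n_bg = len(background)
    out = np.empty((len(masks), n))
    rows_per_mask = n * n_bg
    chunk = max(1, batch_rows // rows_per_mask)
    for start in range(0, len(masks), chunk):
        block = masks[start : start + chunk]
        hybrids = np.empty((len(block), n, n_bg, d))
        for mi, mask in enumerate(block):
            h = np.broadcast_to(background[None, :, :], (n, n_bg, d)).copy()
            h[:, :, mask] = X[:, None, mask]
            hybrids[mi] = h
        scores = np.asarray(model_fn(hybrids.reshape(-1, d)), dtype=float)
        scores = scores.reshape(len(block), n, n_bg)
        out[start : start + chunk] = scores.mean(axis=2)
    return out


def _exact_shapley(model_fn, X, background):
    n, d = X.shape
    masks = []
    for bits in range(2**d):
        masks.append(np.array([(bits >> j) & 1 for j in range(d)], dtype=bool))
    v = _coalition_values(model_fn, X, background, masks)
    fact = [factorial(i) for i in range(d + 1)]
    phi = np.zeros((n, d))
    for bits in range(2**d):
        size = bin(bits).count("1")
        for j in range(d):
            if bits >> j & 1:
                continue
            wgt = fact[size] * fact[d - size - 1] / fact[d]
            phi[:, j] += wgt * (v[bits | (1 << j)] - v[bits])
    base = float(v[0].mean())  # v(empty) identical across samples by definition
    return phi, base


def _kernel_masks(d: int, n_coalitions: int, rng: np.random.Generator):
    """Coalition masks plus kernel weights: complete size groups first,
    then sampled coalitions carrying the residual kernel mass."""
    size_mass = {s: (d - 1) / (s * (d - s)) for s in range(1, d)}
    masks, weights = [], []
    remaining = dict(size_mass)
    budget = n_coalitions
    # pair sizes (s, d-s) from the outside in; each group is cheap and heavy
    order = sorted(size_mass, key=lambda s: min(s, d - s))
    for s in order:
        if s not in remaining:
            continue
        n_group = comb(d, s)
        if n_group > budget:
            continue
        w_each = size_mass[s] / n_group
        for idx in _all_subsets_of_size(d, s):
            mask = np.zeros(d, dtype=bool)
            mask[list(idx)] = True
            masks.append(mask)
            weights.append(w_each)
        budget -= n_group
        del remaining[s]
    if remaining and budget > 0:
        sizes = np.array(sorted(remaining))
        pmass = np.array([remaining[s] for s in sizes])
        pmass = pmass / pmass.sum()
        total_rest = sum(remaining.values())
        drawn = rng.choice(sizes, size=budget, p=pmass)
        for s in drawn:
            idx = rng.choice(d, size=int(s), replace=False)
            mask = np.zeros(d, dtype=bool)
            mask[idx] = True
            masks.append(mask)
            weights.append(total_rest / budget)
    return masks, np.asarray(weights)


def _all_subsets_of_size(d, s):
    from itertools import combinations

    return combinations(range(d), s)


def _kernel_shapley(model_fn, X, background, n_coalitions, rng):
    n, d = X.shape
    if n_coalitions < 2 * d:
        raise ValueError("sampled estimator needs n_coalitions >= 2d")
    masks, w = _kernel_masks(d, n_coalitions, rng)
    Z = np.vstack([m.astype(float) for m in masks])
    v = _coalition_values(model_fn, X, background, masks)  # (M, n)
    base = float(
        np.asarray(model_fn(background), dtype=float).mean()
    )
    fx = np.asarray(model_fn(X), dtype=float)
    # constrained WLS via KKT: minimize ||W^(1/2)(Z phi - t)||, 1' phi fixed
    A = Z.T * w @ Z + 1e-10 * np.eye(d)
    ones = np.ones(d)
    K = np.zeros((d + 1, d + 1))
    K[:d, :d] = A
    K[:d, d] = ones
    K[d, :d] = ones
    phi = np.empty((n, d))
    rhs = np.empty(d + 1)
    for i in range(n):
        t = v[:, i] - base
        rhs[:d] = Z.T @ (w * t)
        rhs[d] = fx[i] - base
        sol = np.linalg.solve(K, rhs)
        phi[i] = sol[:d]
    return phi, base


def shapley_values(
    model_fn,
    X: np.ndarray,
    background: np.ndarray,
    n_coalitions: int | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> Explanation:
    """Shapley attributions of ``model_fn`` scores for the rows of X.

    Exact enumeration when d <= 12 and no coalition budget is given;
    otherwise the kernel WLS estimator with ``n_coalitions`` coalitions
    (default ``max(2d + 2, 256)``). Deterministic per seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    if d <= 12 and n_coalitions is None:
        phi, base = _exact_shapley(model_fn, X, background)
    else:
        m = n_coalitions if n_coalitions is not None else max(2 * d + 2, 256)
        m = min(m, 2**d - 2) if d < 30 else m
        phi, base = _kernel_shapley(model_fn, X, background, m, rng)
    return Explanation(
        phi=phi,
        base_value=base,
        X=X,
        feature_names=feature_names or [f"x{j}" for j in range(d)],
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
    )


def summary_ranking(expl: Explanation) -> pd.DataFrame:
    """Features ordered by descending mean |phi|; ties keep column order."""
    mean_abs = np.abs(expl.phi).mean(axis=0)
    order = np.lexsort((np.arange(len(mean_abs)), -mean_abs))
    return pd.DataFrame(
        {
            "feature": [expl.feature_names[j] for j in order],
            "rank": np.arange(1, len(order) + 1),
            "mean_abs_phi": mean_abs[order],
            "column_index": order,
        }
    )


def dependence_table(
    expl: Explanation, primary: str, secondary: str
) -> pd.DataFrame:
    """Scatter-ready rows: primary value, its phi, and the coloring feature."""
    for name in (primary, secondary):
        if name not in expl.feature_names:
            raise KeyError(f"unknown feature {name!r}")
    jp = expl.feature_names.index(primary)
    js = expl.feature_names.index(secondary)
    return pd.DataFrame(
        {
            "sample_id": expl.sample_ids,
            "primary_value": expl.X[:, jp],
            "phi_primary": expl.phi[:, jp],
            "secondary_value": expl.X[:, js],
        }
    )


def beeswarm_export(expl: Explanation, top_m: int | None = None) -> pd.DataFrame:
    """Long-format table (n x top_m rows) for beeswarm-style rendering."""
    ranking = summary_ranking(expl)
    top_m = expl.n_features if top_m is None else top_m
    if top_m > expl.n_features:
        raise ValueError("top_m exceeds the number of features")
    rows = []
    for _, rec in ranking.head(top_m).iterrows():
        j = int(rec["column_index"])
        for i in range(expl.n_samples):
            rows.append(
                {
                    "feature": rec["feature"],
                    "rank": int(rec["rank"]),
                    "phi": expl.phi[i, j],
                    "feature_value": expl.X[i, j],
                    "sample_id": expl.sample_ids[i],
                }
            )
    return pd.DataFrame(rows)
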