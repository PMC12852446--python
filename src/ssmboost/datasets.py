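"""Synthetic ICU cohort generator.

Emulates the statistical shape of a sepsis early-warning dataset: 49 numeric
per-stay aggregates of vitals and labs, correlated within clinical panels,
with a nonlinear (main effects + pairwise interactions) risk signal carried by
a small set of designated features. Because the informative features and their
signs are chosen by construction, downstream explanation output has a known
ground truth — the property every end-to-end test leans on.

Real EHR cohorts differ in ways this generator does not model: longitudinal
sampling, informative missingness, unit heterogeneity and label noise from
imperfect phenotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io import Dataset, VALID_COHORT_WINDOWS

# name -> (low, high, unit, panel). 49 per-stay aggregate features; ranges are
# plausible adult-ICU values so explanation tables read like clinical output.
FEATURE_CATALOG: dict[str, tuple[float, float, str, str]] = {
    "heart_rate_min": (40, 100, "bpm", "vitals"),
    "heart_rate_max": (70, 180, "bpm", "vitals"),
    "heart_rate_mean": (55, 130, "bpm", "vitals"),
    "sbp_min": (60, 120, "mmHg", "vitals"),
    "sbp_max": (100, 200, "mmHg", "vitals"),
    "sbp_mean": (80, 150, "mmHg", "vitals"),
    "dbp_min": (30, 70, "mmHg", "vitals"),
    "dbp_max": (60, 120, "mmHg", "vitals"),
    "dbp_mean": (45, 90, "mmHg", "vitals"),
    "mbp_min": (40, 85, "mmHg", "vitals"),
    "mbp_max": (70, 140, "mmHg", "vitals"),
    "mbp_mean": (55, 105, "mmHg", "vitals"),
    "resp_rate_min": (8, 20, "breaths/min", "vitals"),
    "resp_rate_max": (16, 45, "breaths/min", "vitals"),
    "resp_rate_mean": (12, 30, "breaths/min", "vitals"),
    "temperature_min": (35.0, 37.5, "degC", "vitals"),
    "temperature_max": (36.5, 40.5, "degC", "vitals"),
    "temperature_mean": (35.8, 38.5, "degC", "vitals"),
    "spo2_min": (75, 98, "%", "vitals"),
    "spo2_mean": (90, 100, "%", "vitals"),
    "glucose_min": (50, 140, "mg/dL", "chemistry"),
    "glucose_max": (100, 350, "mg/dL", "chemistry"),
    "glucose_mean": (80, 220, "mg/dL", "chemistry"),
    "creatinine_min": (0.3, 2.0, "mg/dL", "chemistry"),
    "creatinine_max": (0.5, 5.0, "mg/dL", "chemistry"),
    "bun_min": (5, 40, "mg/dL", "chemistry"),
    "bun_max": (10, 90, "mg/dL", "chemistry"),
    "sodium_min": (125, 142, "mEq/L", "chemistry"),
    "sodium_max": (136, 155, "mEq/L", "chemistry"),
    "potassium_min": (2.8, 4.5, "mEq/L", "chemistry"),
    "potassium_max": (3.8, 6.5, "mEq/L", "chemistry"),
    "chloride_min": (90, 108, "mEq/L", "chemistry"),
    "chloride_max": (100, 120, "mEq/L", "chemistry"),
    "bicarbonate_min": (12, 26, "mEq/L", "chemistry"),
    "bicarbonate_max": (20, 34, "mEq/L", "chemistry"),
    "aniongap_min": (6, 16, "mEq/L", "chemistry"),
    "aniongap_max": (10, 28, "mEq/L", "chemistry"),
    "lactate_min": (0.5, 3.0, "mmol/L", "chemistry"),
    "lactate_max": (1.0, 8.0, "mmol/L", "chemistry"),
    "platelet_min": (30, 350, "1e9/L", "hematology"),
    "platelet_max": (120, 550, "1e9/L", "hematology"),
    "wbc_min": (2, 14, "1e9/L", "hematology"),
    "wbc_max": (5, 30, "1e9/L", "hematology"),
    "hemoglobin_min": (6, 13, "g/dL", "hematology"),
    "hemoglobin_max": (9, 16, "g/dL", "hematology"),
    "inr_min": (0.9, 1.6, "ratio", "hematology"),
    "inr_max": (1.0, 3.5, "ratio", "hematology"),
    "ptt_min": (22, 40, "s", "hematology"),
    "ptt_max": (28, 90, "s", "hematology"),
}

assert len(FEATURE_CATALOG) == 49

# Signed main effects on the latent (standardized) feature scale. Low platelet
# count, low MAP and low SpO2 raise risk; high creatinine and lactate raise it.
DEFAULT_SIGNAL_FEATURES: dict[str, float] = {
    "platelet_min": -1.3,
    "creatinine_max": 1.3,
    "mbp_min": -1.2,
    "lactate_max": 1.0,
    "spo2_min": -1.0,
}

# Interactions sized on par with the main effects: simultaneous renal failure
# and hypotension (or thrombocytopenia and hyperlactatemia) are super-additive
# risks, and the nonlinear share of the signal is what separates ensemble
# learners from a purely linear baseline.
DEFAULT_INTERACTIONS: list[tuple[str, str, float]] = [
    ("creatinine_max", "mbp_min", -1.4),
    ("platelet_min", "lactate_max", -1.2),
]

# Pre-SMOTE class counts (negative, positive) per cohort window.
WINDOW_CLASS_COUNTS: dict[int, tuple[int, int]] = {
    7: (534, 378),
    14: (531, 336),
    28: (501, 319),
}

_WITHIN_PANEL_RHO = 0.3


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 912
    d: int = 49
    prevalence: float = 0.41
    signal_features: dict[str, float] | None = None
    interaction_pairs: list[tuple[str, str, float]] | None = None
    noise_sd: float = 0.5
    cohort_window: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        names = feature_names(self.d)
        if self.signal_features is None:
            # default signal set restricted to the features actually present
            self.signal_features = {
                k: v for k, v in DEFAULT_SIGNAL_FEATURES.items() if k in names
            } or {names[0]: 1.0}
        if self.interaction_pairs is None:
            self.interaction_pairs = [
                (a, b, g) for a, b, g in DEFAULT_INTERACTIONS
                if a in self.signal_features and b in self.signal_features
            ]
        missing = set(self.signal_features) - set(names)
        if missing:
            raise ValueError(f"signal features not in feature set: {sorted(missing)}")
        if self.d < len(self.signal_features):
            raise ValueError("d must be >= number of signal features")
        if self.cohort_window is not None and self.cohort_window not in VALID_COHORT_WINDOWS:
            raise ValueError(f"cohort_window must be in {VALID_COHORT_WINDOWS}")


def feature_names(d: int = 49) -> list[str]:
    """First ``d`` catalog names, extended with generic labs if ``d > 49``."""
    base = list(FEATURE_CATALOG)
    if d <= len(base):
        return base[:d]
    return base + [f"lab_{i}" for i in range(d - len(base))]


def _panel_correlation(names: list[str]) -> np.ndarray:
    """Block-structured correlation: rho within a clinical panel, 0 across."""
    panels = [FEATURE_CATALOG.get(n, (0, 1, "", "other"))[3] for n in names]
    panels = np.asarray(panels)
    same = panels[:, None] == panels[None, :]
    corr = np.where(same, _WITHIN_PANEL_RHO, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _latent_to_clinical(z: np.ndarray, names: list[str]) -> np.ndarray:
    """Map standard-normal latents to per-feature clinical ranges.

    Range midpoint becomes the mean and one sixth of the range the SD, so
    ~99.7% of draws fall inside the catalog's (low, high) interval.
    """
    lows = np.array([FEATURE_CATALOG.get(n, (0.0, 1.0, "", ""))[0] for n in names])
    highs = np.array([FEATURE_CATALOG.get(n, (0.0, 1.0, "", ""))[1] for n in names])
    mid = (lows + highs) / 2.0
    sd = (highs - lows) / 6.0
    return mid + sd * z


def _solve_intercept(signal: np.ndarray, prevalence: float, tol: float = 1e-3) -> float:
    """Bisection on [-20, 20] so mean sigmoid(b0 + signal) hits prevalence."""
    lo, hi = -20.0, 20.0
    f = lambda b0: float(np.mean(expit(b0 + signal))) - prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            "target prevalence unreachable for this signal (degenerate cohort)"
        )
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < tol * 1e-2:
            break
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec) -> Dataset:
    """Draw one cohort: correlated Gaussian features, logistic-model labels.

    Latents Z ~ N(0, panel-block correlation); features are affine maps of Z
    into clinical ranges; the risk score is a linear + pairwise-interaction
    function of the signal latents plus N(0, noise_sd) noise, with the
    intercept solved so the expected prevalence matches ``spec.prevalence``.
    """
    rng = np.random.default_rng(spec.seed)
    names = feature_names(spec.d)
    corr = _panel_correlation(names)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n, spec.d)) @ chol.T
    X = _latent_to_clinical(z, names)

    col = {n: i for i, n in enumerate(names)}
    signal = np.zeros(spec.n)
    for name, beta in spec.signal_features.items():
        signal += beta * z[:, col[name]]
    for a, b, gamma in spec.interaction_pairs:
        signal += gamma * z[:, col[a]] * z[:, col[b]]
    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=spec.n)

    b0 = _solve_intercept(signal, spec.prevalence)
    p = expit(b0 + signal)
    y = (rng.random(spec.n) < p).astype(int)

    prefix = f"w{spec.cohort_window}_" if spec.cohort_window else ""
    cohort = (
        np.full(spec.n, spec.cohort_window) if spec.cohort_window is not None else None
    )
    return Dataset(
        X=X,
        y=y,
        feature_names=names,
        sample_ids=[f"{prefix}s{i}_{spec.seed}" for i in range(spec.n)],
        cohort=cohort,
    )


def table1_cohort(window: int, seed: int = 0) -> Dataset:
    """Cohort with the exact pre-balancing class counts of one study window.

    Draws an oversized cohort and truncates to exactly the published
    negative:positive counts (7-day 534:378, 14-day 531:336, 28-day 501:319),
    keeping generated row order.
    """
    if window not in WINDOW_CLASS_COUNTS:
        raise ValueError(f"window must be one of {sorted(WINDOW_CLASS_COUNTS)}")
    n_neg, n_pos = WINDOW_CLASS_COUNTS[window]
    n_total = n_neg + n_pos
    pool_n = int(2.5 * n_total)
    for attempt in range(5):
        spec = CohortSpec(
            n=pool_n,
            prevalence=n_pos / n_total,
            cohort_window=window,
            seed=seed + 1000 * attempt,
        )
        pool = generate_cohort(spec)
        pos_idx = np.flatnonzero(pool.y == 1)[:n_pos]
        neg_idx = np.flatnonzero(pool.y == 0)[:n_neg]
        if len(pos_idx) == n_pos and len(neg_idx) == n_neg:
            keep = np.sort(np.concatenate([pos_idx, neg_idx]))
            return pool.subset(keep)
        pool_n *= 2
    raise RuntimeError("could not realize the requested class counts")
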