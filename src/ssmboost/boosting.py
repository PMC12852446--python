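"""Sample-reweighting boosting loop and multi-paradigm ensemble modes.

Three ensemble paradigms over a registry of heterogeneous base learners:

* ``ada`` — discrete AdaBoost: per-round weighted error eps_t, learner weight
  alpha_t = 0.5 ln((1-eps_t)/eps_t), multiplicative weight update
  w_i <- w_i exp(-alpha_t y_i yhat_i) / Z_t with labels and predictions in
  {-1, +1} (misclassified samples gain weight), final score
  sum_t alpha_t h_t(x).
* ``gbm`` — stagewise additive modeling of the logistic loss: each round fits
  the pseudo-residuals, a scalar step is line-searched, and the model adds
  eta_lr * step * h_t(x).
* ``rf`` — bagging: B learners on bootstrap resamples, scores averaged.

The base-learner set H spans the native gated-SSM learner and decision
stumps plus adapters over established tree libraries (XGBoost, LightGBM,
random-forest-style and depth-limited CART trees) and a logistic baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .io import Dataset
from .mamba_tab import MambaTabClassifier

logger = logging.getLogger("ssmboost")

_ALPHA_CAP_EPS = 1e-10  # eps clipped here when a round is perfect/hopeless
_MODES = ("ada", "gbm", "rf")


def init_weights(n: int) -> np.ndarray:
    """Uniform initial sample weights w_i = 1/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.full(n, 1.0 / n)


def weighted_error(w: np.ndarray, y: np.ndarray, yhat: np.ndarray) -> float:
    """eps = sum of weights on misclassified samples (labels in {-1,+1})."""
    w = np.asarray(w, dtype=float)
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if not (len(w) == len(y) == len(yhat)):
        raise ValueError("w, y, yhat must have equal length")
    return float(np.sum(w * (y != yhat)))


def compute_alpha(eps: float) -> float:
    """Learner weight alpha = 0.5 ln((1-eps)/eps), capped at eps -> {0, 1}."""
    eps = float(np.clip(eps, _ALPHA_CAP_EPS, 1.0 - _ALPHA_CAP_EPS))
    return 0.5 * np.log((1.0 - eps) / eps)


def update_weights(
    w: np.ndarray, alpha: float, y: np.ndarray, yhat: np.ndarray
) -> tuple[np.ndarray, float]:
    """Multiplicative reweighting w'_i = w_i exp(-alpha y_i yhat_i) / Z.

    Returns the renormalized weights and the normalizer Z. For alpha > 0 the
    misclassified samples (y yhat = -1) gain weight.
    """
    w = np.asarray(w, dtype=float)
    numer = w * np.exp(-alpha * np.asarray(y) * np.asarray(yhat))
    Z = float(numer.sum())
    if Z <= 0:
        raise FloatingPointError("degenerate normalizer in weight update")
    return numer / Z, Z


class DecisionStump(BaseEstimator, ClassifierMixin):
    """Axis-aligned threshold classifier minimizing weighted 0-1 error.

    Enumerates midpoint thresholds on every feature and both polarities;
    ties resolve to the first (lowest feature index, lowest threshold)
    candidate, so fits are fully deterministic.
    """

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        n, d = X.shape
        w = (
            np.full(n, 1.0 / n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float) / np.sum(sample_weight)
        )
        ypm = 2 * y - 1
        best = (np.inf, 0, -np.inf, 1)
        for j in range(d):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys, ws = X[order, j], ypm[order], w[order]
            # err(theta) for polarity +1 (predict +1 when x > theta)
            # candidate thresholds: below the smallest point, and midpoints
            # of strictly increasing gaps (a midpoint of equal values would
            # not actually separate them)
            valid = np.concatenate(([True], xs[:-1] < xs[1:]))
            thresholds = np.concatenate(([xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0))
            # weight of positives at or below each threshold position
            below_pos = np.concatenate(([0.0], np.cumsum(ws * (ys > 0))[:-1]))
            below_neg = np.concatenate(([0.0], np.cumsum(ws * (ys < 0))[:-1]))
            total_neg = np.sum(ws * (ys < 0))
            # polarity +1: wrong = positives below + negatives above
            err_plus = (below_pos + (total_neg - below_neg))[valid]
            err_minus = 1.0 - err_plus
            thresholds = thresholds[valid]
            for errs, pol in ((err_plus, 1), (err_minus, -1)):
                k = int(np.argmin(errs))
                if errs[k] < best[0] - 1e-15:
                    best = (float(errs[k]), j, float(thresholds[k]), pol)
        self.error_, self.feature_, self.threshold_, self.polarity_ = best
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "feature_")
        X = np.asarray(X, dtype=float)
        return self.polarity_ * np.where(X[:, self.feature_] > self.threshold_, 1.0, -1.0)

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X):
        p = expit(2.0 * self.decision_function(X))
        return np.column_stack([1 - p, p])


def _make_base_learner(kind: str, hyper: dict, seed: int):
    """Instantiate one member of the heterogeneous base-learner set H."""
    hyper = dict(hyper or {})
    if kind == "mamba_tab":
        return MambaTabClassifier(random_state=seed, **hyper)
    if kind == "stump":
        return DecisionStump()
    if kind == "logistic":
        hyper.setdefault("max_iter", 1000)
        return LogisticRegression(**hyper)
    if kind == "xgboost":
        import xgboost as xgb

        hyper.setdefault("n_estimators", 60)
        hyper.setdefault("max_depth", 3)
        hyper.setdefault("learning_rate", 0.2)
        return xgb.XGBClassifier(
            random_state=seed, verbosity=0, eval_metric="logloss",
            n_jobs=1, **hyper,
        )
    if kind == "lightgbm":
        import lightgbm as lgb

        hyper.setdefault("n_estimators", 60)
        hyper.setdefault("max_depth", 3)
        return lgb.LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **hyper)
    if kind == "rf_tree":
        hyper.setdefault("max_features", "sqrt")
        return DecisionTreeClassifier(random_state=seed, **hyper)
    if kind == "gbdt_tree":
        hyper.setdefault("max_depth", 3)
        return DecisionTreeClassifier(random_state=seed, **hyper)
    raise ValueError(f"unknown base learner kind {kind!r}")


BASE_LEARNERS = ("mamba_tab", "stump", "logistic", "xgboost", "lightgbm",
                 "rf_tree", "gbdt_tree")


def _score(learner, X: np.ndarray) -> np.ndarray:
    """Continuous decision score of a fitted base learner (logit scale)."""
    if hasattr(learner, "decision_function"):
        return np.asarray(learner.decision_function(X), dtype=float)
    p = np.clip(learner.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _hard_pm1(learner, X: np.ndarray) -> np.ndarray:
    return np.where(_score(learner, X) > 0, 1.0, -1.0)


@dataclass
class EnsembleConfig:
    """Configuration of one ensemble fit."""

    mode: str = "ada"
    base_learner: str = "mamba_tab"
    eta_lr: float = 0.1
    n_bags: int = 10
    bootstrap: bool = True
    base_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.base_learner not in BASE_LEARNERS:
            raise ValueError(f"base_learner must be one of {BASE_LEARNERS}")
        if self.eta_lr <= 0:
            raise ValueError("eta_lr must be positive")
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")


@dataclass
class BoostingState:
    """Fitted trajectory of one boosting run."""

    mode: str
    w: np.ndarray
    alpha: list[float]
    eps: list[float]
    Z: list[float]
    learners: list
    T: int
    intercept: float = 0.0
    w_history: list[np.ndarray] = field(default_factory=list)


class BoostedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Boosting/bagging ensemble over heterogeneous weak learners.

    Parameters
    ----------
    mode : {"ada", "gbm", "rf"}
        Ensemble paradigm (AdaBoost reweighting, stagewise gradient
        boosting of the logistic loss, or bootstrap aggregation).
    base_learner : str
        Member of the base-learner set (see ``BASE_LEARNERS``).
    n_rounds : int
        Boosting rounds T (ada/gbm) or number of bagged learners B (rf).
    eta_lr : float
        Shrinkage applied to the line-searched step in gbm mode.
    bootstrap : bool
        rf mode only; ``False`` fits every member on the full sample
        (degenerate bagging, useful for testing).
    base_params : dict or None
        Hyperparameters forwarded to the base learner.
    random_state : int
        Master seed; per-round learner seeds are derived by fixed offsets.
    """

    def __init__(
        self,
        mode: str = "ada",
        base_learner: str = "mamba_tab",
        n_rounds: int = 5,
        eta_lr: float = 0.1,
        bootstrap: bool = True,
        base_params: dict | None = None,
        random_state: int = 0,
    ):
        self.mode = mode
        self.base_learner = base_learner
        self.n_rounds = n_rounds
        self.eta_lr = eta_lr
        self.bootstrap = bootstrap
        self.base_params = base_params
        self.random_state = random_state

    def _round_seed(self, t: int, attempt: int = 0) -> int:
        return (self.random_state * 1009 + 7919 * (t + 1) + 104729 * attempt) % (
            2**31 - 1
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        bad = set(np.unique(y)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be in {{0,1}}; found {sorted(bad)}")
        EnsembleConfig(
            mode=self.mode, base_learner=self.base_learner, eta_lr=self.eta_lr,
            n_bags=self.n_rounds, base_params=self.base_params or {},
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        ypm = 2.0 * y - 1.0
        fitter = {"ada": self._fit_ada, "gbm": self._fit_gbm, "rf": self._fit_rf}[
            self.mode
        ]
        self.state_ = fitter(X, y, ypm)
        return self

    # -- ada ---------------------------------------------------------------
    def _fit_ada(self, X, y, ypm) -> BoostingState:
        n = len(y)
        w = init_weights(n)
        state = BoostingState(
            mode="ada", w=w, alpha=[], eps=[], Z=[], learners=[], T=self.n_rounds,
            w_history=[w.copy()],
        )
        for t in range(self.n_rounds):
            learner, yhat, eps = None, None, 1.0
            for attempt in range(3):
                cand = _make_base_learner(
                    self.base_learner, self.base_params or {},
                    self._round_seed(t, attempt),
                )
                # mean-1 scaling: relative weights unchanged, but tree
                # libraries keep sane hessian sums (min_child_weight etc.)
                cand.fit(X, y, sample_weight=w * n)
                cand_hat = _hard_pm1(cand, X)
                cand_eps = weighted_error(w, ypm, cand_hat)
                if cand_eps < eps:
                    learner, yhat, eps = cand, cand_hat, cand_eps
                if cand_eps < 0.5:
                    break
            if eps >= 0.5:
                logger.warning(
                    "ada round %d: weighted error %.3f >= 0.5 after retries; "
                    "stopping early", t, eps,
                )
                break
            alpha = compute_alpha(eps)
            state.learners.append(learner)
            state.alpha.append(alpha)
            state.eps.append(eps)
            if eps <= _ALPHA_CAP_EPS:
                state.Z.append(1.0)
                state.w_history.append(w.copy())
                break  # perfect round: capped alpha, nothing left to reweight
            w, Z = update_weights(w, alpha, ypm, yhat)
            state.Z.append(Z)
            state.w_history.append(w.copy())
        state.w = w
        return state

    # -- gbm ---------------------------------------------------------------
    def _fit_gbm(self, X, y, ypm) -> BoostingState:
        n = len(y)
        p0 = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        intercept = np.log(p0 / (1 - p0))
        F = np.full(n, intercept)
        state = BoostingState(
            mode="gbm", w=init_weights(n), alpha=[], eps=[], Z=[], learners=[],
            T=self.n_rounds, intercept=intercept,
        )
        for t in range(self.n_rounds):
            resid = y - expit(F)  # negative gradient of logistic loss
            if np.allclose(resid, 0.0):
                break
            pseudo_y = (resid > 0).astype(int)
            w_abs = np.abs(resid)
            if w_abs.sum() == 0:
                break
            learner = _make_base_learner(
                self.base_learner, self.base_params or {}, self._round_seed(t)
            )
            learner.fit(X, pseudo_y, sample_weight=w_abs / w_abs.mean())
            h = _hard_pm1(learner, X)

            def loss(gamma):
                z = F + gamma * h
                return float(np.sum(np.logaddexp(0.0, z) - y * z))

            res = minimize_scalar(loss, bounds=(0.0, 8.0), method="bounded")
            gamma = float(res.x) if res.fun <= loss(0.0) else 0.0
            step = self.eta_lr * gamma
            F = F + step * h
            state.learners.append(learner)
            state.alpha.append(step)
            state.eps.append(float(np.mean((h > 0) != (resid > 0))))
            state.Z.append(float(np.sum(np.logaddexp(0.0, F) - y * F)))
        return state

    # -- rf ----------------------------------------------------------------
    def _fit_rf(self, X, y, ypm) -> BoostingState:
        n = len(y)
        state = BoostingState(
            mode="rf", w=init_weights(n), alpha=[], eps=[], Z=[], learners=[],
            T=self.n_rounds,
        )
        for b in range(self.n_rounds):
            seed = self._round_seed(b)
            if self.bootstrap:
                rng = np.random.default_rng(seed)
                idx = rng.integers(0, n, size=n)
                # bootstrap may drop a class entirely on tiny data; redraw once
                if len(np.unique(y[idx])) < 2:
                    idx = rng.integers(0, n, size=n)
                    if len(np.unique(y[idx])) < 2:
                        idx = np.arange(n)
            else:
                idx = np.arange(n)
            learner = _make_base_learner(
                self.base_learner, self.base_params or {}, seed
            )
            learner.fit(X[idx], y[idx], sample_weight=None)
            state.learners.append(learner)
            state.alpha.append(1.0 / self.n_rounds)
        return state

    # -- prediction --------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        """Continuous ensemble score (logit-like; monotone in risk)."""
        check_is_fitted(self, "state_")
        X = np.asarray(X, dtype=float)
        st = self.state_
        if not st.learners:
            if st.mode == "gbm":
                return np.full(len(X), st.intercept)
            raise ValueError("ensemble has no fitted learners")
        if st.mode == "ada":
            margin = np.zeros(len(X))
            for alpha, learner in zip(st.alpha, st.learners):
                margin += alpha * _hard_pm1(learner, X)
            return margin
        if st.mode == "gbm":
            F = np.full(len(X), st.intercept)
            for step, learner in zip(st.alpha, st.learners):
                F += step * _hard_pm1(learner, X)
            return F
        # rf: average probability, reported on the logit scale
        p = np.mean(
            [np.clip(l.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
             for l in st.learners],
            axis=0,
        )
        return np.log(p / (1 - p))

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def predict_pm1(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


def _learner_bundle(learner) -> dict:
    if isinstance(learner, MambaTabClassifier):
        return learner.to_bundle()
    if isinstance(learner, DecisionStump):
        return {
            "format": "ssmboost.stump", "version": 1,
            "feature": int(learner.feature_), "threshold": float(learner.threshold_),
            "polarity": int(learner.polarity_),
            "n_features_in": int(learner.n_features_in_),
        }
    raise NotImplementedError(
        f"serialization covers native learners only; got {type(learner).__name__} "
        "(library-backed members carry their own persistence formats)"
    )


def _learner_from_bundle(bundle: dict):
    if bundle.get("format") == "ssmboost.mamba_tab":
        return MambaTabClassifier.from_bundle(bundle)
    if bundle.get("format") == "ssmboost.stump":
        stump = DecisionStump()
        stump.feature_ = bundle["feature"]
        stump.threshold_ = bundle["threshold"]
        stump.polarity_ = bundle["polarity"]
        stump.n_features_in_ = bundle["n_features_in"]
        stump.classes_ = np.array([0, 1])
        stump.error_ = float("nan")
        return stump
    raise ValueError(f"unknown learner bundle format {bundle.get('format')!r}")


def save_ensemble(clf: BoostedEnsembleClassifier, path) -> None:
    """Serialize a fitted ensemble of native learners to a JSON bundle."""
    import json
    from pathlib import Path

    check_is_fitted(clf, "state_")
    st = clf.state_
    bundle = {
        "format": "ssmboost.ensemble",
        "version": 1,
        "hyper": clf.get_params(),
        "n_features_in": int(clf.n_features_in_),
        "mode": st.mode,
        "alpha": list(map(float, st.alpha)),
        "eps": list(map(float, st.eps)),
        "Z": list(map(float, st.Z)),
        "intercept": float(st.intercept),
        "T": int(st.T),
        "learners": [_learner_bundle(l) for l in st.learners],
    }
    Path(path).write_text(json.dumps(bundle))


def load_ensemble(path) -> BoostedEnsembleClassifier:
    import json
    from pathlib import Path

    bundle = json.loads(Path(path).read_text())
    if bundle.get("format") != "ssmboost.ensemble":
        raise ValueError("not an ensemble bundle")
    clf = BoostedEnsembleClassifier(**bundle["hyper"])
    clf.classes_ = np.array([0, 1])
    clf.n_features_in_ = bundle["n_features_in"]
    clf.state_ = BoostingState(
        mode=bundle["mode"],
        w=np.empty(0),
        alpha=bundle["alpha"],
        eps=bundle["eps"],
        Z=bundle["Z"],
        learners=[_learner_from_bundle(b) for b in bundle["learners"]],
        T=bundle["T"],
        intercept=bundle["intercept"],
    )
    return clf


def fit_ensemble(
    data: Dataset, config: EnsembleConfig, T: int, seed: int = 0
) -> BoostingState:
    """Fit a boosting ensemble on a Dataset and return its state trajectory."""
    clf = BoostedEnsembleClassifier(
        mode=config.mode,
        base_learner=config.base_learner,
        n_rounds=T if config.mode != "rf" else config.n_bags,
        eta_lr=config.eta_lr,
        bootstrap=config.bootstrap,
        base_params=config.base_params,
        random_state=seed,
    )
    clf.fit(data.X, data.y)
    state = clf.state_
    state._estimator = clf  # retained so predict_ensemble can reuse it
    return state


def predict_ensemble(state: BoostingState, X: np.ndarray):
    """Scores and hard {-1,+1} labels from a fitted :class:`BoostingState`."""
    est = getattr(state, "_estimator", None)
    if est is None:
        raise ValueError("state was not produced by fit_ensemble")
    scores = est.decision_function(X)
    return scores, np.where(scores > 0, 1, -1)
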