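"""Gaussian-process Bayesian optimization over hyperparameters and modes.

A Matérn-5/2 GP surrogate maps encoded configurations (continuous dimensions
rescaled to [0, 1], optionally on a log scale; categoricals one-hot) to an
observed performance Perf in [0, 1] — here typically mean validation AUC.
Expected improvement, maximized by random multi-start with local refinement,
proposes the next configuration. Histories from earlier runs can seed the
surrogate (incremental reuse), skipping the part of the initial design that
was already observed.

Two distinct symbols named eta elsewhere in the framework are kept apart:
``eta_lr`` (gradient-boosting shrinkage) and ``eta_sens`` (the softmax
sensitivity of ensemble-mode selection, constrained to [1e-5, 0.1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

ETA_SENS_BOUNDS = (1e-5, 0.1)


@dataclass
class RealDim:
    name: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError(f"bounds for {self.name!r} must be finite")
        if not self.low < self.high:
            raise ValueError(f"low < high required for {self.name!r}")
        if self.log and self.low <= 0:
            raise ValueError(f"log dimension {self.name!r} needs low > 0")

    def to_unit(self, v: float) -> float:
        if self.log:
            return (np.log(v) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
        return (v - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = float(np.clip(u, 0.0, 1.0))
        if self.log:
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        return float(self.low + u * (self.high - self.low))


@dataclass
class CategoricalDim:
    name: str
    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"categorical {self.name!r} must be non-empty")
        self.values = tuple(self.values)


class SearchSpace:
    """Mixed continuous/categorical search space with unit-cube encoding."""

    def __init__(self, dims: list[RealDim | CategoricalDim]):
        if not dims:
            raise ValueError("search space must have at least one dimension")
        self.dims = list(dims)

    @property
    def n_encoded(self) -> int:
        return sum(
            1 if isinstance(d, RealDim) else len(d.values) for d in self.dims
        )

    def encode(self, config: dict) -> np.ndarray:
        out = []
        for d in self.dims:
            if isinstance(d, RealDim):
                out.append(d.to_unit(config[d.name]))
            else:
                onehot = np.zeros(len(d.values))
                onehot[d.values.index(config[d.name])] = 1.0
                out.extend(onehot)
        return np.asarray(out)

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[dict]:
        """Quasi-random (Sobol) draws on continuous dims, uniform categoricals."""
        real_dims = [d for d in self.dims if isinstance(d, RealDim)]
        if real_dims:
            sob = qmc.Sobol(d=len(real_dims), scramble=True,
                            seed=int(rng.integers(2**31)))
            unit = sob.random(n)
        configs = []
        for i in range(n):
            cfg = {}
            ri = 0
            for d in self.dims:
                if isinstance(d, RealDim):
                    cfg[d.name] = d.from_unit(unit[i, ri])
                    ri += 1
                else:
                    cfg[d.name] = d.values[rng.integers(len(d.values))]
            configs.append(cfg)
        return configs

    def perturb(self, config: dict, rng: np.random.Generator,
                scale: float = 0.05) -> dict:
        """Local move: Gaussian step on continuous dims, occasional category flip."""
        cfg = dict(config)
        for d in self.dims:
            if isinstance(d, RealDim):
                u = d.to_unit(cfg[d.name]) + rng.normal(0.0, scale)
                cfg[d.name] = d.from_unit(u)
            elif rng.random() < 0.1:
                cfg[d.name] = d.values[rng.integers(len(d.values))]
        return cfg

    def contains(self, config: dict) -> bool:
        for d in self.dims:
            v = config[d.name]
            if isinstance(d, RealDim):
                if not (d.low - 1e-12 <= v <= d.high + 1e-12):
                    return False
            elif v not in d.values:
                return False
        return True


@dataclass
class OptState:
    """History and incumbent of one optimization run."""

    observations: list[tuple[dict, float]] = field(default_factory=list)
    failed: list[dict] = field(default_factory=list)
    eta_sens: float = 0.1
    kernel_: str | None = None

    @property
    def incumbent(self) -> tuple[dict, float]:
        if not self.observations:
            raise ValueError("no observations yet")
        best = max(self.observations, key=lambda cp: cp[1])
        return best


def gp_fit(observations: list[tuple[dict, float]], space: SearchSpace,
           seed: int = 0) -> GaussianProcessRegressor:
    """Fit a Matérn-5/2 GP with fitted noise to (config, Perf) observations."""
    if len(observations) < 2:
        raise ValueError("need at least 2 observations to fit the surrogate")
    X = np.vstack([space.encode(c) for c, _ in observations])
    y = np.array([p for _, p in observations])
    alpha = 1e-10
    if len(np.unique(X, axis=0)) < len(X):
        alpha = 1e-8  # duplicate configurations: jitter the diagonal
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.ones(X.shape[1]),
        length_scale_bounds=(1e-2, 1e2),
        nu=2.5,
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-12, 1e-1))
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=alpha, normalize_y=True,
        n_restarts_optimizer=2, random_state=seed,
    )
    with warnings.catch_warnings():
        # marginal-likelihood maximization routinely stops at the bound on
        # small designs; the fitted surrogate is still usable
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def ei_closed_form(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    """E[max(f - best, 0)] for f ~ N(mu, sigma^2); sigma = 0 handled exactly."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    imp = mu - best
    out = np.maximum(imp, 0.0)
    pos = sigma > 0
    z = np.zeros_like(mu)
    np.divide(imp, sigma, out=z, where=pos)
    out = np.where(pos, imp * norm.cdf(z) + sigma * norm.pdf(z), out)
    return out


def expected_improvement(surrogate: GaussianProcessRegressor,
                         candidate: np.ndarray, incumbent_value: float) -> float:
    """EI of one encoded candidate under a fitted surrogate."""
    mu, sd = surrogate.predict(np.atleast_2d(candidate), return_std=True)
    return float(ei_closed_form(mu, sd, incumbent_value)[0])


def select_mode(perfs: dict[str, float], eta_sens: float, seed: int = 0
                ) -> tuple[dict[str, float], str]:
    """Softmax mode selection P(h_j) ∝ exp(eta_sens * Perf(h_j)).

    At the lower sensitivity bound (1e-5) the distribution is effectively
    uniform; at 0.1 it still only mildly favors the best mode, so the
    sampled mode explores while the final fit takes the argmax.
    """
    if not perfs:
        raise ValueError("perfs must be non-empty")
    lo, hi = ETA_SENS_BOUNDS
    if not lo <= eta_sens <= hi:
        raise ValueError(f"eta_sens must lie in [{lo}, {hi}]")
    names = list(perfs)
    vals = np.array([perfs[m] for m in names], dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("Perf values must lie in [0, 1]")
    z = eta_sens * vals
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    probs = dict(zip(names, p))
    rng = np.random.default_rng(seed)
    sampled = rng.choice(names, p=p)
    return probs, str(sampled)


class GPOptimizer:
    """Sequential model-based optimizer (GP surrogate + expected improvement).

    Parameters
    ----------
    space : SearchSpace
    n_initial : int, default 5
        Quasi-random initial design size (reduced by any reused history).
    n_candidates : int, default 256
        Random multi-start candidates per acquisition maximization.
    random_state : int, default 0
    """

    def __init__(self, space: SearchSpace, n_initial: int = 5,
                 n_candidates: int = 256, random_state: int = 0):
        self.space = space
        self.n_initial = n_initial
        self.n_candidates = n_candidates
        self.random_state = random_state

    def optimize(self, objective, budget: int,
                 history: list[tuple[dict, float]] | None = None) -> OptState:
        """Run up to ``budget`` objective evaluations; returns the history.

        Objective errors are recorded as failed configurations (budget
        consumed, excluded from the surrogate). Deterministic per seed for a
        deterministic objective.
        """
        rng = np.random.default_rng(self.random_state)
        state = OptState(observations=list(history or []))
        seen = [c for c, _ in state.observations]

        def evaluate(cfg: dict) -> None:
            try:
                perf = float(objective(cfg))
            except Exception:
                state.failed.append(cfg)
                return
            state.observations.append((cfg, perf))
            seen.append(cfg)

        spent = 0
        design = self.space.sample(rng, max(self.n_initial, 1))
        # stratify the design over the categorical product so small budgets
        # still touch every (e.g.) mode x learner combination
        cat_dims = [d for d in self.space.dims if isinstance(d, CategoricalDim)]
        if cat_dims:
            from itertools import product

            combos = list(product(*(d.values for d in cat_dims)))
            for i, cfg in enumerate(design):
                for d, val in zip(cat_dims, combos[i % len(combos)]):
                    cfg[d.name] = val
        for cfg in design:
            if spent >= budget:
                break
            if cfg in seen:
                continue  # incremental reuse: already observed
            evaluate(cfg)
            spent += 1

        while spent < budget:
            fresh = [cp for cp in state.observations]
            if len(fresh) >= 2:
                gp = gp_fit(fresh, self.space, seed=self.random_state)
                state.kernel_ = str(gp.kernel_)
                best_perf = state.incumbent[1]
                cands = self.space.sample(rng, self.n_candidates)
                X = np.vstack([self.space.encode(c) for c in cands])
                mu, sd = gp.predict(X, return_std=True)
                ei = ei_closed_form(mu, sd, best_perf)
                pick = cands[int(np.argmax(ei))]
                # local refinement around the best random candidate
                best_ei = float(ei.max())
                for _ in range(32):
                    cand = self.space.perturb(pick, rng)
                    val = expected_improvement(gp, self.space.encode(cand), best_perf)
                    if val > best_ei:
                        best_ei, pick = val, cand
                nxt = pick
            else:
                nxt = self.space.sample(rng, 1)[0]
            evaluate(nxt)
            spent += 1
        return state


def optimize(objective, space: SearchSpace, budget: int,
             history: list[tuple[dict, float]] | None = None,
             seed: int = 0) -> OptState:
    """Functional wrapper over :class:`GPOptimizer`."""
    opt = GPOptimizer(space, random_state=seed)
    return opt.optimize(objective, budget, history=history)
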