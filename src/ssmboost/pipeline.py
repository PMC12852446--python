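"""End-to-end workflow: simulate -> tune -> train -> evaluate -> explain.

One run handles each requested cohort window independently: generate (or
load) the cohort, tune the ensemble mode and hyperparameters by GP Bayesian
optimization against inner-CV AUC, refit the argmax configuration, evaluate
with stratified k-fold CV (SMOTE inside training folds), and export Shapley
explanation tables for the refit model. A master seed fans out to per-stage
seeds by fixed offsets so all JSON outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesopt import (
    CategoricalDim,
    OptState,
    RealDim,
    SearchSpace,
    select_mode,
)
from .bayesopt import GPOptimizer
from .boosting import BoostedEnsembleClassifier
from .datasets import CohortSpec, generate_cohort
from .explain import beeswarm_export, dependence_table, shapley_values, summary_ranking
from .io import Dataset, RunConfig, write_table
from .metrics import MetricReport, cross_validate
from .smote import SMOTE

logger = logging.getLogger("ssmboost")

# fixed seed offsets per stage so one master seed reproduces everything
_STAGE_OFFSET = {"simulate": 11, "tune": 23, "train": 37, "evaluate": 53,
                 "explain": 71}
_SEED_MOD = 2**31 - 1


def stage_seed(master: int, stage: str, window: int = 0) -> int:
    return (master * 1000003 + _STAGE_OFFSET[stage] * 8191 + window * 127) % _SEED_MOD


def default_search_space(
    base_learners: tuple[str, ...] = ("mamba_tab", "xgboost"),
) -> SearchSpace:
    """Joint space over ensemble mode, base learner and shared knobs."""
    return SearchSpace(
        [
            CategoricalDim("mode", ("gbm", "ada", "rf")),
            CategoricalDim("base_learner", tuple(base_learners)),
            RealDim("n_rounds", 1.0, 4.99),
            RealDim("eta_lr", 0.05, 1.0, log=True),
            RealDim("learning_rate", 0.005, 0.06, log=True),
        ]
    )


def _config_to_estimator(cfg: dict, seed: int, max_epochs: int = 40
                         ) -> BoostedEnsembleClassifier:
    base = cfg["base_learner"]
    if base == "mamba_tab":
        base_params = {
            "learning_rate": cfg.get("learning_rate", 0.02),
            "max_epochs": max_epochs,
            "n_channels": 6,
            "d_state": 3,
        }
    elif base == "xgboost":
        base_params = {"learning_rate": max(cfg.get("learning_rate", 0.02) * 10, 0.05)}
    else:
        base_params = {}
    return BoostedEnsembleClassifier(
        mode=cfg["mode"],
        base_learner=base,
        n_rounds=int(cfg.get("n_rounds", 3)),
        eta_lr=cfg.get("eta_lr", 0.3),
        base_params=base_params,
        random_state=seed,
    )


def tune_ensemble(
    data: Dataset,
    budget: int = 8,
    seed: int = 0,
    inner_folds: int = 3,
    smote: SMOTE | None = None,
    space: SearchSpace | None = None,
    history: list | None = None,
    subsample: int | None = 500,
    max_epochs: int = 30,
) -> tuple[OptState, dict, dict]:
    """GP-BO over mode + hyperparameters; Perf = mean inner-CV AUC.

    Returns the optimization state, the incumbent configuration, and the
    per-mode softmax selection probabilities (sensitivity eta_sens = 0.1).
    The objective runs on an optional stratified subsample so a tuning call
    stays cheap relative to the final fit.
    """
    space = space or default_search_space()
    rng = np.random.default_rng(seed)
    if subsample is not None and data.n_samples > subsample:
        pos = np.flatnonzero(data.y == 1)
        neg = np.flatnonzero(data.y == 0)
        frac = subsample / data.n_samples
        keep = np.sort(
            np.concatenate(
                [
                    rng.choice(pos, size=max(int(len(pos) * frac), inner_folds), replace=False),
                    rng.choice(neg, size=max(int(len(neg) * frac), inner_folds), replace=False),
                ]
            )
        )
        tune_data = data.subset(keep)
    else:
        tune_data = data

    def objective(cfg: dict) -> float:
        est = _config_to_estimator(cfg, seed=seed, max_epochs=max_epochs)
        report = cross_validate(est, tune_data, k_cv=inner_folds, seed=seed,
                                smote=smote)
        return report.mean("auc")

    # design size 6 covers the full (mode x base-learner) grid when possible
    opt = GPOptimizer(space, n_initial=min(6, budget), random_state=seed)
    state = opt.optimize(objective, budget=budget, history=history)
    best_cfg, _ = state.incumbent
    per_mode: dict[str, float] = {}
    for cfg, perf in state.observations:
        m = cfg["mode"]
        per_mode[m] = max(per_mode.get(m, 0.0), perf)
    probs, _sampled = select_mode(per_mode, eta_sens=0.1, seed=seed)
    return state, dict(best_cfg), probs


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, artifacts, stage status."""

    config: dict
    master_seed: int
    stages: dict = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    version: str = "0.1.0"

    def add_stage(self, name: str, status: str, seconds: float) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 2)}

    def add_artifact(self, path: Path) -> None:
        self.artifacts.append(str(path))

    def validate(self) -> None:
        missing = [p for p in self.artifacts if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing artifacts: {missing}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full workflow for every requested cohort window."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), master_seed=config.seed)
    smote = (
        SMOTE(k_neighbors=config.smote_k, random_state=config.seed)
        if config.smote
        else None
    )
    for window in config.windows:
        t0 = time.time()
        try:
            spec = CohortSpec(
                n=config.n_samples,
                d=config.n_features,
                prevalence=config.prevalence,
                cohort_window=window,
                seed=stage_seed(config.seed, "simulate", window),
            )
            data = generate_cohort(spec)
            cohort_path = out / f"cohort_{window}d.csv"
            write_table(data, cohort_path)
            sidecar = out / f"cohort_{window}d.json"
            sidecar.write_text(json.dumps({
                "n": spec.n, "d": spec.d, "prevalence": spec.prevalence,
                "noise_sd": spec.noise_sd, "seed": spec.seed,
                "cohort_window": window,
                "signal_features": spec.signal_features,
            }, indent=2))
            manifest.add_artifact(cohort_path)
            manifest.add_artifact(sidecar)
            manifest.add_stage(f"simulate_{window}d", "ok", time.time() - t0)
        except Exception as exc:  # pragma: no cover - defensive
            manifest.add_stage(f"simulate_{window}d", f"failed: {exc}", time.time() - t0)
            raise

        # tune
        t0 = time.time()
        if config.mode == "bayes":
            state, best_cfg, mode_probs = tune_ensemble(
                data,
                budget=config.tune_budget,
                seed=stage_seed(config.seed, "tune", window),
                smote=smote,
            )
            trace_path = out / f"tune_trace_{window}d.jsonl"
            with open(trace_path, "w") as fh:
                for cfg, perf in state.observations:
                    fh.write(json.dumps({"config": cfg, "perf": perf,
                                         "seed": stage_seed(config.seed, "tune", window)})
                             + "\n")
            manifest.add_artifact(trace_path)
            manifest.stages[f"tune_{window}d_mode_probs"] = mode_probs
        else:
            best_cfg = {"mode": config.mode, "base_learner": "mamba_tab",
                        "n_rounds": config.rounds, "eta_lr": 0.3,
                        "learning_rate": 0.02}
        manifest.add_stage(f"tune_{window}d", "ok", time.time() - t0)

        # evaluate with the tuned configuration
        t0 = time.time()
        est = _config_to_estimator(
            best_cfg, seed=stage_seed(config.seed, "train", window), max_epochs=40
        )
        report = cross_validate(est, data, k_cv=config.k_cv,
                                seed=stage_seed(config.seed, "evaluate", window),
                                smote=smote)
        report.extra["best_config"] = best_cfg
        report_path = out / f"metrics_{window}d.json"
        report.to_json(report_path)
        table_path = out / f"metrics_{window}d.csv"
        report.to_table_row(f"tuned_{best_cfg['mode']}").to_csv(table_path)
        manifest.add_artifact(report_path)
        manifest.add_artifact(table_path)
        manifest.add_stage(f"evaluate_{window}d", "ok", time.time() - t0)

        # final refit + explanation exports
        t0 = time.time()
        mu = data.X.mean(axis=0)
        sd = np.maximum(data.X.std(axis=0), 1e-12)
        Xs = (data.X - mu) / sd
        y_fit = data.y
        if smote is not None:
            Xs_fit, y_fit, _ = smote.fit_resample(Xs, data.y)
        else:
            Xs_fit = Xs
        final = _config_to_estimator(
            best_cfg, seed=stage_seed(config.seed, "train", window), max_epochs=40
        )
        final.fit(Xs_fit, y_fit)
        rng = np.random.default_rng(stage_seed(config.seed, "explain", window))
        n_expl = min(100, data.n_samples)
        expl_idx = rng.choice(data.n_samples, size=n_expl, replace=False)
        bg_idx = rng.choice(data.n_samples, size=min(50, data.n_samples),
                            replace=False)
        expl = shapley_values(
            final.decision_function,
            Xs[expl_idx],
            Xs[bg_idx],
            n_coalitions=max(2 * data.n_features + 2, 192),
            seed=stage_seed(config.seed, "explain", window),
            feature_names=data.feature_names,
            sample_ids=[data.sample_ids[i] for i in expl_idx],
        )
        ranking = summary_ranking(expl)
        shap_path = out / f"shap_summary_{window}d.csv"
        ranking.to_csv(shap_path, index=False)
        bees_path = out / f"beeswarm_{window}d.csv"
        beeswarm_export(expl, top_m=min(20, data.n_features)).to_csv(
            bees_path, index=False
        )
        top = ranking.iloc[0]["feature"]
        second = ranking.iloc[1]["feature"]
        dep_path = out / f"dependence_{window}d.csv"
        dependence_table(expl, top, second).to_csv(dep_path, index=False)
        for p in (shap_path, bees_path, dep_path):
            manifest.add_artifact(p)
        manifest.add_stage(f"explain_{window}d", "ok", time.time() - t0)

    manifest_path = out / "manifest.json"
    manifest.add_artifact(manifest_path)
    manifest.to_json(manifest_path)
    manifest.validate()
    return manifest
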