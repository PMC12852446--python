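"""Boosting engine vs a brute-force AdaBoost oracle, plus mode properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmboost import (
    BoostedEnsembleClassifier,
    DecisionStump,
    compute_alpha,
    init_weights,
    update_weights,
    weighted_error,
)


def adaboost_oracle(X, y01, T):
    """Textbook discrete AdaBoost, written as an explicit loop for the test.

    Returns the (eps, alpha, weight-trajectory) it produces with the same
    deterministic stump learner.
    """
    n = len(y01)
    ypm = 2.0 * np.asarray(y01) - 1.0
    w = np.full(n, 1.0 / n)
    eps_hist, alpha_hist, w_hist = [], [], [w.copy()]
    for _ in range(T):
        # mean-1 weight scaling, the engine's convention for base learners
        stump = DecisionStump().fit(X, y01, sample_weight=w * n)
        pred = stump.decision_function(X)
        eps = float(np.sum(w[pred != ypm]))
        if eps >= 0.5 or eps <= 0:
            break
        alpha = 0.5 * np.log((1 - eps) / eps)
        numer = w * np.exp(-alpha * ypm * pred)
        w = numer / numer.sum()
        eps_hist.append(eps)
        alpha_hist.append(alpha)
        w_hist.append(w.copy())
    return eps_hist, alpha_hist, w_hist


@pytest.fixture
def toy_1d():
    """Six 1-D points that no single stump separates."""
    X = np.arange(6, dtype=float).reshape(-1, 1)
    y = np.array([1, 1, 0, 1, 0, 0])
    return X, y


class TestPrimitives:
    def test_init_weights_uniform(self):
        np.testing.assert_array_equal(init_weights(4), [0.25] * 4)
        np.testing.assert_array_equal(init_weights(1), [1.0])
        for n in (2, 7, 1000):
            assert init_weights(n).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            init_weights(0)

    def test_weighted_error_cases(self):
        w = np.full(4, 0.25)
        y = np.array([1, 1, -1, -1])
        assert weighted_error(w, y, y) == 0.0
        assert weighted_error(w, y, -y) == 1.0
        yhat = np.array([1, -1, -1, -1])  # one of four wrong
        assert weighted_error(w, y, yhat) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            weighted_error(w, y, y[:2])

    def test_alpha_formula_and_monotonicity(self):
        assert compute_alpha(0.5) == pytest.approx(0.0, abs=1e-12)
        assert compute_alpha(0.1) == pytest.approx(0.5 * np.log(9.0))
        grid = np.linspace(0.01, 0.99, 50)
        alphas = [compute_alpha(e) for e in grid]
        assert np.all(np.diff(alphas) < 0)
        assert np.isfinite(compute_alpha(0.0)) and np.isfinite(compute_alpha(1.0))

    def test_update_weights_two_sample_closed_form(self):
        """One of two uniform samples wrong at alpha = 0.5 ln 9 -> weight 0.9."""
        w = np.array([0.5, 0.5])
        y = np.array([1.0, 1.0])
        yhat = np.array([1.0, -1.0])
        alpha = 0.5 * np.log(9.0)
        w2, Z = update_weights(w, alpha, y, yhat)
        e = np.exp(alpha)
        assert w2[1] == pytest.approx(e / (e + 1 / e))
        assert w2[1] == pytest.approx(0.9)
        assert Z > 0

    def test_update_weights_all_correct_identity(self):
        w = np.array([0.1, 0.2, 0.7])
        y = np.ones(3)
        w2, _ = update_weights(w, 1.3, y, y)
        np.testing.assert_allclose(w2, w, atol=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8),
        st.floats(-2.0, 2.0),
        st.integers(0, 2**31 - 1),
    )
    def test_update_weights_simplex_and_permutation(self, raw_w, alpha, seed):
        rng = np.random.default_rng(seed)
        w = np.array(raw_w) / np.sum(raw_w)
        y = rng.choice([-1.0, 1.0], size=len(w))
        yhat = rng.choice([-1.0, 1.0], size=len(w))
        w2, _ = update_weights(w, alpha, y, yhat)
        assert w2.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w2 >= 0)
        perm = rng.permutation(len(w))
        w2p, _ = update_weights(w[perm], alpha, y[perm], yhat[perm])
        np.testing.assert_allclose(w2p, w2[perm], atol=1e-15)


class TestAdaMode:
    def test_matches_oracle_trace(self, toy_1d):
        """eps, alpha and weight trajectories equal brute force to 1e-10."""
        X, y = toy_1d
        clf = BoostedEnsembleClassifier(
            mode="ada", base_learner="stump", n_rounds=3, random_state=0
        ).fit(X, y)
        eps_o, alpha_o, w_o = adaboost_oracle(X, y, 3)
        st_ = clf.state_
        assert len(st_.eps) == len(eps_o) > 0
        np.testing.assert_allclose(st_.eps, eps_o, atol=1e-10)
        np.testing.assert_allclose(st_.alpha, alpha_o, atol=1e-10)
        for got, want in zip(st_.w_history, w_o):
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_predictions_match_oracle_vote(self, toy_1d):
        X, y = toy_1d
        clf = BoostedEnsembleClassifier(
            mode="ada", base_learner="stump", n_rounds=3, random_state=0
        ).fit(X, y)
        _, alpha_o, _ = adaboost_oracle(X, y, 3)
        margin = np.zeros(len(y))
        w = np.full(len(y), 1 / len(y))
        ypm = 2.0 * y - 1
        for alpha in alpha_o:
            stump = DecisionStump().fit(X, y, sample_weight=w * len(y))
            pred = stump.decision_function(X)
            margin += alpha * pred
            numer = w * np.exp(-alpha * ypm * pred)
            w = numer / numer.sum()
        np.testing.assert_array_equal(clf.predict(X), (margin > 0).astype(int))

    def test_weights_stay_on_simplex(self, small_cohort):
        clf = BoostedEnsembleClassifier(
            mode="ada", base_learner="stump", n_rounds=6, random_state=0
        ).fit(small_cohort.X, small_cohort.y)
        for w in clf.state_.w_history:
            assert abs(w.sum() - 1.0) < 1e-12 and np.all(w >= 0)

    def test_larger_oracle_instances(self):
        """Trajectory identity on random instances (n <= 12, T <= 4)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 13))
            X = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            clf = BoostedEnsembleClassifier(
                mode="ada", base_learner="stump", n_rounds=4, random_state=0
            ).fit(X, y)
            eps_o, alpha_o, _ = adaboost_oracle(X, y, 4)
            np.testing.assert_allclose(clf.state_.eps, eps_o, atol=1e-10)
            np.testing.assert_allclose(clf.state_.alpha, alpha_o, atol=1e-10)

    def test_single_round_sign(self, toy_1d):
        X, y = toy_1d
        clf = BoostedEnsembleClassifier(
            mode="ada", base_learner="stump", n_rounds=1, random_state=0
        ).fit(X, y)
        stump = clf.state_.learners[0]
        expected = clf.state_.alpha[0] * stump.decision_function(X)
        np.testing.assert_allclose(clf.decision_function(X), expected)


class TestGbmMode:
    def test_training_loss_non_increasing(self, small_cohort):
        clf = BoostedEnsembleClassifier(
            mode="gbm", base_learner="stump", n_rounds=8, eta_lr=0.5,
            random_state=0,
        ).fit(small_cohort.X, small_cohort.y)
        losses = clf.state_.Z  # per-round training logistic loss
        assert np.all(np.diff(losses) <= 1e-6)

    def test_vanishing_shrinkage_reduces_to_intercept(self, small_cohort):
        clf = BoostedEnsembleClassifier(
            mode="gbm", base_learner="stump", n_rounds=5, eta_lr=1e-5,
            random_state=0,
        ).fit(small_cohort.X, small_cohort.y)
        F = clf.decision_function(small_cohort.X)
        np.testing.assert_allclose(F, clf.state_.intercept, atol=1e-3)


class TestRfMode:
    def test_single_learner_identity_without_bootstrap(self, small_cohort):
        clf = BoostedEnsembleClassifier(
            mode="rf", base_learner="stump", n_rounds=1, bootstrap=False,
            random_state=0,
        ).fit(small_cohort.X, small_cohort.y)
        single = DecisionStump().fit(small_cohort.X, small_cohort.y)
        np.testing.assert_array_equal(
            clf.predict(small_cohort.X), single.predict(small_cohort.X)
        )

    def test_variance_decreases_with_bag_count(self, small_cohort):
        """Score variance across bootstrap seeds shrinks as B grows."""
        X, y = small_cohort.X, small_cohort.y
        probe = X[:40]
        variances = []
        for B in (1, 5, 25):
            scores = [
                BoostedEnsembleClassifier(
                    mode="rf", base_learner="rf_tree", n_rounds=B,
                    base_params={"max_depth": 3}, random_state=seed,
                )
                .fit(X, y)
                .decision_function(probe)
                for seed in range(8)
            ]
            variances.append(np.mean(np.var(scores, axis=0)))
        assert variances[0] > variances[1] > variances[2]


class TestValidation:
    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="0,1"):
            BoostedEnsembleClassifier(base_learner="stump").fit(
                np.zeros((4, 2)), np.array([0, 1, 2, 1])
            )

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            BoostedEnsembleClassifier(mode="bagboost", base_learner="stump").fit(
                np.zeros((4, 2)), np.array([0, 1, 0, 1])
            )
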