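"""Boundary-aware mixtures: likelihood correctness, recovery, predictions."""

import math

import numpy as np
import pytest
import scipy.special
import scipy.stats

import saqmap as sq
from saqmap.mixtures import (
    FittedALDVMM,
    FittedBetaMix,
    simulate_aldvmm,
    simulate_betamix,
)

from conftest import random_design

PSI, FLOOR = 0.957, -0.391


def _true_aldvmm(columns):
    return FittedALDVMM(
        beta=np.array([[0.45, 0.30, 0.02, 0.03, 0.05, 0.10],
                       [0.80, 0.25, 0.02, 0.02, 0.04, 0.08]]),
        sigma=np.array([0.14, 0.05]),
        delta=np.array([0.4]),
        psi=PSI, floor=FLOOR, columns=columns,
    )


def _true_betamix(columns):
    return FittedBetaMix(
        gamma=np.array([-3.0, 1.2, 0.3, 0.4, 0.5, 1.0]),
        delta=np.array([[0.4, 1.0, 0.1, 0.2, 0.3, 0.5]]),
        phi=np.array([18.0]),
        omega=np.array([]),
        lower=FLOOR, columns=columns,
    )


class TestALDVMM:
    def test_degenerate_single_component_matches_ols_direction(self):
        X = random_design(600, 20)
        rng = np.random.default_rng(21)
        y = np.clip(np.asarray(X) @ np.array([0.4, 0.3, 0.02, 0.03, 0.05, 0.1])
                    + rng.normal(0, 0.05, 600), FLOOR, PSI)
        model = sq.fit_aldvmm(X, y, K=1, n_starts=1)
        ols = sq.fit_ols(X, y)
        assert np.allclose(model.beta[0], ols.beta, atol=0.01)

    def test_gap_values_rejected(self):
        X = random_design(20, 22)
        y = np.full(20, 0.98)  # inside (psi, 1)
        with pytest.raises(ValueError, match="gap"):
            sq.fit_aldvmm(X, y)

    def test_two_component_recovery(self):
        X = random_design(5000, 23)
        true = _true_aldvmm(tuple(X.columns))
        y = simulate_aldvmm(true, X, 1, seed=24)[0]
        model = sq.fit_aldvmm(X, y, K=2, n_starts=3, seed=0)
        assert np.allclose(model.beta, true.beta, atol=0.08)
        assert np.allclose(model.sigma, true.sigma, atol=0.02)
        assert np.allclose(model.weights, true.weights, atol=0.08)

    def test_predictions_never_exceed_one(self, design_and_utility):
        X, y = design_and_utility
        model = sq.fit_aldvmm(X, y, n_starts=3, seed=1)
        pred = sq.predict_mixture(model, X)
        assert pred.max() <= 1.0
        assert pred.min() >= FLOOR

    def test_k2_loglik_at_least_k1(self, design_and_utility):
        X, y = design_and_utility
        m1 = sq.fit_aldvmm(X, y, K=1, n_starts=2, seed=2)
        m2 = sq.fit_aldvmm(X, y, K=2, n_starts=4, seed=2)
        assert m2.loglik >= m1.loglik - 1e-6


class TestBetaMix:
    def test_symmetric_null_gives_zero_link(self):
        # y* symmetric around 0.5 and independent of the covariates: the
        # fitted mean link is ~0 everywhere
        X = random_design(3000, 25)
        rng = np.random.default_rng(26)
        ystar = rng.beta(8.0, 8.0, 3000)
        y = FLOOR + (1.0 - FLOOR) * ystar
        model = sq.fit_betamix(X, y, C=1, n_starts=1)
        assert np.all(np.abs(model.delta[0]) < 0.12)
        mu = scipy.special.expit(np.asarray(X) @ model.delta[0])
        assert np.allclose(mu, 0.5, atol=0.02)

    def test_out_of_bounds_rejected(self):
        X = random_design(10, 27)
        with pytest.raises(ValueError, match="outside"):
            sq.fit_betamix(X, np.full(10, -0.5))

    def test_single_component_recovery(self):
        X = random_design(5000, 28)
        true = _true_betamix(tuple(X.columns))
        y = simulate_betamix(true, X, 1, seed=29)[0]
        model = sq.fit_betamix(X, y, C=1, n_starts=3, seed=0)
        assert np.allclose(model.gamma, true.gamma, atol=0.35)
        assert np.allclose(model.delta[0], true.delta[0], atol=0.12)
        assert model.phi[0] == pytest.approx(true.phi[0], rel=0.12)

    def test_prediction_bounded_and_ceiling_limit(self):
        X = random_design(50, 30)
        model = _true_betamix(tuple(X.columns))
        pred = sq.predict_mixture(model, X)
        assert np.all(pred <= 1.0)
        forced = FittedBetaMix(
            gamma=np.array([50.0, 0, 0, 0, 0, 0]), delta=model.delta,
            phi=model.phi, omega=model.omega, lower=FLOOR,
            columns=model.columns)
        assert sq.predict_mixture(forced, X) == pytest.approx(np.ones(50), abs=1e-6)


class TestPredictionOracle:
    def test_aldvmm_prediction_matches_million_draw_monte_carlo(self):
        X = random_design(3, 31)
        model = _true_aldvmm(tuple(X.columns))
        pred = sq.predict_mixture(model, X)
        draws = simulate_aldvmm(model, X, 1_000_000, seed=32)
        mc_mean = draws.mean(axis=0)
        mc_se = draws.std(axis=0) / 1000.0
        assert np.all(np.abs(pred - mc_mean) <= 3.0 * mc_se)

    def test_betamix_prediction_matches_million_draw_monte_carlo(self):
        X = random_design(3, 33)
        model = _true_betamix(tuple(X.columns))
        pred = sq.predict_mixture(model, X)
        draws = simulate_betamix(model, X, 1_000_000, seed=34)
        mc_mean = draws.mean(axis=0)
        mc_se = draws.std(axis=0) / 1000.0
        assert np.all(np.abs(pred - mc_mean) <= 3.0 * mc_se)

    def test_no_boundary_mass_limit_returns_linear_index(self):
        X = random_design(20, 35)
        model = FittedALDVMM(
            beta=np.array([[0.5, 0.1, 0.01, 0.01, 0.02, 0.05]]),
            sigma=np.array([1e-4]), delta=np.array([]),
            psi=PSI, floor=FLOOR, columns=tuple(X.columns))
        pred = sq.predict_mixture(model, X)
        assert np.allclose(pred, np.asarray(X) @ model.beta[0], atol=1e-6)


class TestLoglik:
    def _naive_aldvmm_ll(self, model, X, y):
        pi = model.weights
        total = 0.0
        for i in range(len(y)):
            like = 0.0
            for k in range(model.K):
                mu = float(np.asarray(X)[i] @ model.beta[k])
                s = float(model.sigma[k])
                if y[i] >= 1.0:
                    f = scipy.stats.norm.sf((model.psi - mu) / s)
                elif math.isclose(y[i], model.floor):
                    f = scipy.stats.norm.cdf((model.floor - mu) / s)
                else:
                    f = scipy.stats.norm.pdf((y[i] - mu) / s) / s
                like += pi[k] * f
            total += math.log(like)
        return total

    def test_matches_naive_per_observation_oracle(self):
        X = random_design(40, 36)
        model = _true_aldvmm(tuple(X.columns))
        y = simulate_aldvmm(model, X, 1, seed=37)[0]
        assert sq.loglik(model, X, y) == pytest.approx(
            self._naive_aldvmm_ll(model, X, y), abs=1e-8)

    def test_doubles_when_data_duplicated(self):
        import pandas as pd
        X = random_design(30, 38)
        model = _true_aldvmm(tuple(X.columns))
        y = simulate_aldvmm(model, X, 1, seed=39)[0]
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        assert sq.loglik(model, X2, y2) == pytest.approx(
            2.0 * sq.loglik(model, X, y), rel=1e-10)

    def test_fitted_parameters_locally_optimal(self, design_and_utility):
        X, y = design_and_utility
        model = sq.fit_aldvmm(X, y, K=2, n_starts=3, seed=3)
        ll_hat = sq.loglik(model, X, y)
        rng = np.random.default_rng(40)
        import dataclasses
        for _ in range(100):
            pert = dataclasses.replace(
                model,
                beta=model.beta + rng.normal(0, 0.01, model.beta.shape),
                sigma=model.sigma * np.exp(rng.normal(0, 0.02, model.K)),
            )
            assert sq.loglik(pert, X, y) <= ll_hat + 1e-6


class TestInvariances:
    def test_label_permutation_leaves_predictions_unchanged(self):
        X = random_design(25, 41)
        model = _true_aldvmm(tuple(X.columns))
        pi = model.weights
        import dataclasses
        flipped = dataclasses.replace(
            model,
            beta=model.beta[::-1].copy(),
            sigma=model.sigma[::-1].copy(),
            delta=np.array([np.log(pi[1] / pi[0])]),
        )
        assert np.allclose(sq.predict_mixture(model, X),
                           sq.predict_mixture(flipped, X), atol=1e-10)

    def test_more_starts_never_lower_likelihood(self, design_and_utility):
        X, y = design_and_utility
        sub = X.iloc[:150]
        ysub = y[:150]
        ll1 = sq.fit_betamix(sub, ysub, n_starts=1, seed=4).loglik
        ll3 = sq.fit_betamix(sub, ysub, n_starts=3, seed=4).loglik
        assert ll3 >= ll1 - 1e-6
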