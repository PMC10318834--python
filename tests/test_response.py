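"""Ordered-logit response mapping and expected-utility conversion."""

import numpy as np
import pandas as pd
import pytest
import scipy.special
from hypothesis import given
from hypothesis import strategies as st

import saqmap as sq
from saqmap.response import (
    RESPONSE_COLUMNS,
    OrderedLogitModel,
    _level_probabilities,
    probabilities_frame,
)

from conftest import random_design


def _resp_design(n, seed):
    return random_design(n, seed).drop(columns="const")


def _simulate_ordinal(X, beta, cuts, seed):
    """Draw levels from the proportional-odds model (logistic latent)."""
    rng = np.random.default_rng(seed)
    index = np.asarray(X) @ beta
    latent = index + rng.logistic(size=len(index))
    return np.searchsorted(np.asarray(cuts), latent, side="left") + 1


class TestFit:
    def test_zero_coefficients_reproduce_empirical_shares(self):
        # with beta fixed at 0, cuts at the logits of the cumulative level
        # frequencies give back exactly the empirical category shares
        rng = np.random.default_rng(51)
        levels = rng.choice([1, 2, 3, 4], size=4000, p=[0.5, 0.3, 0.15, 0.05])
        emp = np.array([(levels == k).mean() for k in range(1, 5)])
        cuts = scipy.special.logit(np.cumsum(emp)[:-1])
        model = OrderedLogitModel(dimension="mo", beta=np.zeros(5), cuts=cuts,
                                  category_levels=(1, 2, 3, 4))
        x = np.zeros((1, 5))
        probs = _level_probabilities(model, x)[0]
        assert np.allclose(probs[:4], emp, atol=1e-12)
        assert probs[4] == 0.0

    def test_parameter_recovery_on_proportional_odds_data(self):
        beta = np.array([-3.0, -0.5, -1.0, -0.8, -2.0])
        cuts = np.array([-5.5, -3.5, -1.5])
        X = _resp_design(5000, 52)
        y = _simulate_ordinal(X, beta, cuts, 53)
        states = pd.DataFrame({d: y for d in sq.DIMENSIONS})
        models = sq.fit_response_models(X, states)
        m = models["pd"]
        se = np.sqrt(np.diag(m.vcov))[: len(beta)]
        assert np.all(np.abs(m.beta - beta) <= 2.5 * se)
        assert np.allclose(m.cuts, cuts, atol=0.3)

    def test_single_category_rejected(self):
        X = _resp_design(50, 54)
        states = pd.DataFrame({d: np.ones(50, dtype=int) for d in sq.DIMENSIONS})
        with pytest.raises(ValueError, match="single"):
            sq.fit_response_models(X, states)

    def test_severity_signs_negative_on_generated_cohort(self, cohort):
        # higher (better) subscales must lower the odds of worse levels:
        # the dominant coefficients come out negative
        df = cohort.data
        models = sq.fit_response_models(sq.response_design(df),
                                        df[["mo", "sc", "ua", "pd", "ad"]])
        for dim in ("mo", "ua", "pd", "ad"):
            assert models[dim].beta.min() < 0
            assert models[dim].beta.sum() < 0


class TestPredictProbabilities:
    @given(st.lists(st.floats(0.0, 100.0), min_size=5, max_size=5))
    def test_probabilities_sum_to_one(self, scores):
        model = OrderedLogitModel(
            dimension="mo",
            beta=np.array([-3.0, -0.5, -1.0, -0.8, -2.0]),
            cuts=np.array([-5.0, -3.0, -1.0]),
            category_levels=(1, 2, 3, 4),
        )
        x = np.asarray(scores)[None, :] / 100.0
        probs = _level_probabilities(model, x)[0]
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert probs[4] == 0.0  # level 5 collapsed out

    def test_extreme_index_puts_all_mass_on_best_level(self):
        model = OrderedLogitModel(
            dimension="mo", beta=np.array([-10.0, 0, 0, 0, 0]),
            cuts=np.array([-2.0, 0.0, 2.0]), category_levels=(1, 2, 3, 4))
        x = np.array([[100.0, 0, 0, 0, 0]])   # index -> -inf
        probs = _level_probabilities(model, x)[0]
        assert probs[0] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_scalar_oracle(self):
        beta = np.array([-2.0, -0.3, -0.7, -0.4, -1.1])
        cuts = np.array([-4.0, -2.5, -0.5])
        x = np.array([0.7, 0.4, 0.6, 0.65, 0.5])
        model = OrderedLogitModel(dimension="pd", beta=beta, cuts=cuts,
                                  category_levels=(1, 2, 3, 4))
        got = _level_probabilities(model, x[None, :])[0]
        index = float(x @ beta)
        sigma = lambda v: 1.0 / (1.0 + np.exp(-v))
        expected = [sigma(cuts[0] - index),
                    sigma(cuts[1] - index) - sigma(cuts[0] - index),
                    sigma(cuts[2] - index) - sigma(cuts[1] - index),
                    1.0 - sigma(cuts[2] - index),
                    0.0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_collapsed_levels_round_trip(self):
        n = 2000
        X = _resp_design(n, 55)
        rng = np.random.default_rng(56)
        levels = rng.choice([1, 3, 5], size=n, p=[0.6, 0.3, 0.1])
        states = pd.DataFrame({d: levels for d in sq.DIMENSIONS})
        models = sq.fit_response_models(X, states)
        probs = sq.predict_probabilities(models, X)
        for d in sq.DIMENSIONS:
            assert models[d].category_levels == (1, 3, 5)
            assert np.all(probs[d][:, [1, 3]] == 0.0)
            assert np.allclose(probs[d].sum(axis=1), 1.0, atol=1e-12)


class TestExpectedUtility:
    def _point_mass(self, level):
        v = np.zeros((1, 5))
        v[0, level - 1] = 1.0
        return {d: v for d in sq.DIMENSIONS}

    def test_full_health_mass_scores_one(self, value_set):
        assert sq.expected_utility(self._point_mass(1), value_set)[0] == 1.0

    def test_worst_mass_scores_floor(self, value_set):
        assert sq.expected_utility(self._point_mass(5), value_set)[0] == \
            pytest.approx(-0.391)

    def test_monte_carlo_agrees_with_closed_form(self, value_set):
        rng = np.random.default_rng(57)
        raw = {d: rng.dirichlet(np.ones(5), size=4) for d in sq.DIMENSIONS}
        exact = sq.expected_utility(raw, value_set)
        n_draws = 200_000
        mc = sq.expected_utility(raw, value_set, method="monte-carlo",
                                 n_draws=n_draws, seed=58)
        # per-dimension decrement draws are independent; bound the MC error
        mc_se = 0.5 / np.sqrt(n_draws)
        assert np.all(np.abs(mc - exact) <= 3.0 * np.sqrt(5) * mc_se)

    def test_mass_shift_to_better_level_never_decreases_utility(self, value_set):
        probs = {d: np.array([[0.2, 0.2, 0.2, 0.2, 0.2]]) for d in sq.DIMENSIONS}
        base = sq.expected_utility(probs, value_set)[0]
        better = {d: v.copy() for d, v in probs.items()}
        better["pd"][0, 0] += 0.1
        better["pd"][0, 3] -= 0.1
        assert sq.expected_utility(better, value_set)[0] >= base

    def test_bounds_hold_for_any_valid_probabilities(self, value_set):
        rng = np.random.default_rng(59)
        probs = {d: rng.dirichlet(np.ones(5), size=50) for d in sq.DIMENSIONS}
        eu = sq.expected_utility(probs, value_set)
        assert np.all(eu <= 1.0)
        assert np.all(eu >= value_set.floor)

    def test_invalid_probabilities_rejected(self, value_set):
        probs = self._point_mass(1)
        probs["mo"] = probs["mo"] * 0.5
        with pytest.raises(ValueError, match="sum"):
            sq.expected_utility(probs, value_set)

    def test_modal_method_scores_argmax_state(self, value_set):
        assert sq.expected_utility(self._point_mass(3), value_set,
                                   method="modal")[0] == pytest.approx(
            sq.utility(sq.EQ5DState(3, 3, 3, 3, 3), value_set))

    def test_probabilities_frame_is_long_and_complete(self):
        probs = self._point_mass(2)
        frame = probabilities_frame(probs, pids=[7])
        assert len(frame) == 25
        assert set(frame.columns) == {"pid", "dimension", "level", "probability"}
        assert frame["probability"].sum() == pytest.approx(5.0)
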