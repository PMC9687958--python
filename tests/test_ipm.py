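"""Chained simulation, conservative load extrapolation, OOS and iAC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hdoe.design import ModelSpec
from hdoe.ipm import (IPMChain, backpropagate_iac, oos_rate, predict_pool,
                      simulate_chain)
from hdoe.regression import UOModel


def _model(terms, coef, rmse=0.0, n=20, load_range=None, factors=("x1",)):
    return UOModel(spec=ModelSpec(terms), coef=np.asarray(coef, float),
                   rmse=rmse, n=n, load_range=load_range, factors=factors)


class TestPredictPool:
    def test_within_range_is_plain_prediction(self):
        m = _model(["1", "load"], [1.0, 0.5], load_range=(2.0, 6.0))
        assert predict_pool(m, {"x1": 0.0}, 4.0) == pytest.approx(3.0)

    def test_excess_load_propagates_with_slope_one(self):
        m = _model(["1", "load"], [1.0, 0.5], load_range=(2.0, 6.0))
        at_max = predict_pool(m, {"x1": 0.0}, 6.0)
        d = 1.7
        assert predict_pool(m, {"x1": 0.0}, 6.0 + d) == pytest.approx(
            at_max + d)

    def test_continuous_at_the_knot(self):
        m = _model(["1", "load"], [0.5, 0.8], load_range=(1.0, 3.0))
        left = predict_pool(m, {"x1": 0.0}, 3.0 - 1e-9)
        right = predict_pool(m, {"x1": 0.0}, 3.0 + 1e-9)
        assert right == pytest.approx(left, abs=1e-6)

    def test_monotone_nondecreasing_beyond_load_max(self):
        m = _model(["1", "load"], [0.5, -0.2], load_range=(1.0, 3.0))
        loads = np.linspace(3.0, 10.0, 30)
        vals = [predict_pool(m, {"x1": 0.0}, lo) for lo in loads]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_below_range_uses_fitted_model_unchanged(self):
        m = _model(["1", "load"], [1.0, 0.5], load_range=(2.0, 6.0))
        assert predict_pool(m, {"x1": 0.0}, 0.0) == pytest.approx(1.0)

    def test_missing_load_raises(self):
        m = _model(["1", "load"], [1.0, 0.5], load_range=(2.0, 6.0))
        with pytest.raises(ValueError, match="load"):
            predict_pool(m, {"x1": 0.0})


def _intercept_chain(values, load_ranges):
    models = [_model(["1"], [values[0]], factors=())]
    for v, lr in zip(values[1:], load_ranges):
        models.append(_model(["1"], [v], load_range=lr, factors=()))
    return models


class TestSimulateChain:
    def test_intercept_only_zero_noise_chain_is_deterministic(self):
        models = _intercept_chain([5.0, 3.0, 2.0],
                                  [(0.0, 10.0), (0.0, 10.0)])
        ipm = IPMChain(models=models, spec_limit=4.0)
        out = simulate_chain(ipm, n_mc=500, seed=0)
        np.testing.assert_allclose(out, 2.0)

    def test_same_seed_bit_identical(self):
        m = _model(["1", "x1"], [0.0, 1.0], rmse=0.3, n=10)
        ipm = IPMChain(models=[m], spec_limit=3.0)
        a = simulate_chain(ipm, n_mc=2000, seed=11)
        b = simulate_chain(ipm, n_mc=2000, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_single_uo_identity_model_reproduces_pp_distribution(self):
        # y = x1 exactly, PP ~ N(0, 1), no residual noise
        m = _model(["1", "x1"], [0.0, 1.0], rmse=0.0, n=100)
        ipm = IPMChain(models=[m], spec_limit=3.0, sigma_pp=1.0)
        out = simulate_chain(ipm, n_mc=100_000, seed=3)
        se_mean = 1.0 / np.sqrt(out.size)
        assert abs(out.mean()) < 4 * se_mean
        assert abs(out.std() - 1.0) < 4 * se_mean

    def test_distribution_stable_across_seeds(self):
        m = _model(["1", "x1"], [0.0, 1.0], rmse=0.2, n=12)
        ipm = IPMChain(models=[m], spec_limit=3.0)
        a = simulate_chain(ipm, n_mc=100_000, seed=1)
        b = simulate_chain(ipm, n_mc=100_000, seed=2)
        ks = stats.ks_2samp(a, b).statistic
        assert ks < 0.02

    def test_extending_load_max_cannot_raise_oos(self):
        """With a fitted load slope < 1, growing the observed load range
        shrinks the slope-one region and simulated DS values only drop."""
        up = _model(["1", "x1"], [5.0, 1.0], rmse=0.0, n=20)
        spec_limit = 6.0
        rates = []
        for hi in (4.5, 5.5, 7.0):
            down = _model(["1", "load"], [1.0, 0.4], rmse=0.0, n=20,
                          load_range=(4.0, hi))
            ipm = IPMChain(models=[up, down], spec_limit=spec_limit)
            s = simulate_chain(ipm, n_mc=40_000, seed=9)
            rates.append(oos_rate(s, spec_limit).rate)
        assert rates[0] >= rates[1] >= rates[2]

    def test_small_n_mc_warns(self):
        m = _model(["1"], [1.0], factors=())
        ipm = IPMChain(models=[m], spec_limit=3.0)
        with pytest.warns(UserWarning, match="unstable"):
            simulate_chain(ipm, n_mc=50, seed=0)

    def test_downstream_model_without_load_range_rejected(self):
        models = [_model(["1"], [1.0], factors=()),
                  _model(["1"], [1.0], factors=())]
        with pytest.raises(ValueError, match="load range"):
            IPMChain(models=models, spec_limit=3.0)


class TestSerialization:
    def test_chain_json_round_trip(self, tmp_path):
        models = [_model(["1", "x1"], [5.0, 0.2], rmse=0.1, n=12),
                  _model(["1", "load"], [1.0, 0.5], rmse=0.05, n=10,
                         load_range=(2.0, 6.0), factors=())]
        ipm = IPMChain(models=models, spec_limit=4.5, n_mc=5_000, seed=3)
        path = tmp_path / "ipm.json"
        ipm.to_json(path)
        back = IPMChain.from_json(path)
        assert back.spec_limit == ipm.spec_limit
        assert back.models[1].load_range == (2.0, 6.0)
        a = simulate_chain(ipm, n_mc=1_000, seed=9)
        b = simulate_chain(back, n_mc=1_000, seed=9)
        np.testing.assert_array_equal(a, b)


class TestOOSRate:
    def test_all_below_spec_is_zero(self):
        assert oos_rate(np.zeros(100), 1.0).rate == 0.0

    def test_all_above_spec_is_one(self):
        assert oos_rate(np.full(50, 2.0), 1.0).rate == 1.0

    def test_three_sigma_tail_of_standard_normal(self):
        rng = np.random.default_rng(0)
        est = oos_rate(rng.standard_normal(10**6), 3.0)
        floor = (1 - 0.9973) / 2  # 0.00135
        assert abs(est.rate - floor) < 4 * est.se

    def test_standard_error_formula(self):
        est = oos_rate(np.array([0.0, 2.0, 2.0, 0.0]), 1.0)
        assert est.se == pytest.approx(np.sqrt(0.5 * 0.5 / 4))


class TestBackpropagateIAC:
    def test_identity_chain_keeps_spec_everywhere(self):
        # pool = 1.0 * load at every downstream UO, zero uncertainty
        models = [_model(["1"], [5.0], factors=())]
        for _ in range(3):
            models.append(_model(["1", "load"], [0.0, 1.0], rmse=0.0, n=30,
                                 load_range=(0.0, 100.0), factors=()))
        ipm = IPMChain(models=models, spec_limit=7.5)
        iac = backpropagate_iac(ipm)
        np.testing.assert_allclose(iac, 7.5)

    def test_linear_inversion_within_training_range(self):
        a, b, spec_limit = 1.0, 0.5, 3.0
        models = [_model(["1"], [2.0], factors=()),
                  _model(["1", "load"], [a, b], rmse=0.0, n=30,
                         load_range=(0.0, 100.0), factors=())]
        ipm = IPMChain(models=models, spec_limit=spec_limit)
        iac = backpropagate_iac(ipm)
        assert iac[-1] == spec_limit
        assert iac[0] == pytest.approx((spec_limit - a) / b)

    def test_spiking_that_extends_range_raises_upstream_iac(self):
        # same slope, wider observed range: the slope-one region starts
        # later, so the invertible region grows and the load limit with it
        spec_limit = 4.0
        out = []
        for hi in (2.0, 6.0):
            models = [_model(["1"], [2.0], factors=()),
                      _model(["1", "load"], [0.5, 0.3], rmse=0.0, n=30,
                             load_range=(0.0, hi), factors=())]
            ipm = IPMChain(models=models, spec_limit=spec_limit)
            out.append(backpropagate_iac(ipm)[0])
        assert out[1] >= out[0]

    def test_nonpositive_slope_with_infeasible_limit_warns_unbounded(self):
        models = [_model(["1"], [2.0], factors=()),
                  _model(["1", "load"], [5.0, -0.1], rmse=0.0, n=30,
                         load_range=(0.0, 10.0), factors=())]
        ipm = IPMChain(models=models, spec_limit=3.0)
        with pytest.warns(UserWarning, match="unbounded"):
            iac = backpropagate_iac(ipm)
        assert np.isinf(iac[0])
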