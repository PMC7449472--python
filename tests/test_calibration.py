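"""Exponential calibration, prediction, out-of-sample R² and model ranking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coiltox import (
    SyntheticConfig,
    builtin_models,
    generate_fleet,
    generate_sessions,
    summarize_fleet,
)
from coiltox.calibration import (
    fit_exponential,
    predict,
    predictive_r2,
    rank_models,
    train_predict_evaluate,
)


def grid_search_exponential(x, y, a_range, b_range, n_grid=201, log_objective=False):
    """Independent oracle: brute-force (a, b) minimizing the fit objective."""
    a_grid = np.linspace(*a_range, n_grid)
    b_grid = np.linspace(*b_range, n_grid)
    best = (np.inf, None, None)
    for a in a_grid:
        fitted = a * np.exp(np.outer(b_grid, x))
        if log_objective:
            sse = ((np.log(y) - np.log(fitted)) ** 2).sum(axis=1)
        else:
            sse = ((y - fitted) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(a), float(b_grid[i]))
    return best


class TestFitExponential:
    @pytest.mark.parametrize("method", ["log_linear_ols", "nonlinear_ls"])
    def test_noiseless_recovery(self, method):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * np.exp(0.5 * x)
        fit = fit_exponential(x, y, method=method)
        assert fit.a == pytest.approx(2.0, rel=1e-9)
        assert fit.b == pytest.approx(0.5, rel=1e-9)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.log_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_data_gives_flat_curve(self):
        fit = fit_exponential([0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert fit.a == pytest.approx(3.0)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.fit_r2 == 1.0  # exact fit to constant data, by convention

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.0, 0.6, 9)
        y = 5.0 * np.exp(8.0 * x) * np.exp(rng.normal(0, 0.2, 9))
        fit = fit_exponential(x, y, method="nonlinear_ls")
        sse_fit = float(np.sum(fit.residuals**2))
        # broad window around the fitted optimum; the fit must beat every
        # grid point and the grid argmin must coincide with it
        sse_grid, a_grid, b_grid = grid_search_exponential(
            x, y, (0.2 * fit.a, 5.0 * fit.a), (fit.b - 5.0, fit.b + 5.0), n_grid=401
        )
        assert sse_fit <= sse_grid + 1e-9
        assert fit.a == pytest.approx(a_grid, rel=0.05)
        assert fit.b == pytest.approx(b_grid, abs=2 * 10.0 / 400)

    def test_rejects_nonpositive_y(self):
        with pytest.raises(ValueError, match="y > 0"):
            fit_exponential([0.0, 1.0, 2.0], [1.0, 0.0, 2.0])

    def test_rejects_degenerate_design(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_exponential([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_exponential([0.0, 1.0], [1.0, 2.0])

    def test_interval_coverage_of_true_rate(self):
        """95% log-scale CI for b covers the truth at roughly nominal rate."""
        covered = 0
        n_fleets = 200
        for seed in range(n_fleets):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.uniform(0.0, 0.6, 9)
            y = 5.0 * np.exp(8.0 * x) * np.exp(rng.normal(0, 0.2, 9))
            fit = fit_exponential(x, y)
            lo, hi = fit.b_conf_int
            covered += lo <= 8.0 <= hi
        assert 0.88 <= covered / n_fleets <= 0.99

    def test_parameter_recovery_median_error(self):
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(20_000 + seed)
            x = rng.uniform(0.0, 0.6, 9)
            y = 5.0 * np.exp(8.0 * x) * np.exp(rng.normal(0, 0.2, 9))
            fit = fit_exponential(x, y)
            errors.append(abs(fit.b - 8.0) / 8.0)
        assert np.median(errors) < 0.10


class TestPredict:
    @pytest.mark.parametrize(
        "a, b, x, expected",
        [(2.0, 0.5, 0.0, 2.0), (2.0, 0.0, 17.3, 2.0), (1.0, math.log(2), 3.0, 8.0)],
    )
    def test_examples(self, a, b, x, expected):
        fit = fit_exponential([0.0, 1.0, 2.0], a * np.exp(b * np.arange(3.0)))
        assert predict(fit, x) == pytest.approx(expected, rel=1e-9)

    def test_positive_everywhere(self):
        fit = fit_exponential([0.0, 1.0, 2.0], [1.0, 2.0, 4.0])
        assert (predict(fit, np.linspace(-5, 5, 11)) > 0).all()


class TestPredictiveR2:
    def test_perfect_prediction(self):
        assert predictive_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        assert predictive_r2([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_reversed_predictions_go_negative(self):
        assert predictive_r2([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-3.0)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            predictive_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(
        obs=st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12, unique=True),
        shift=st.floats(-5.0, 5.0),
    )
    def test_matches_hand_formula(self, obs, shift):
        pred = [o + shift * (i + 1) for i, o in enumerate(obs)]
        obs_arr = np.array(obs)
        expected = 1 - np.sum((obs_arr - np.array(pred)) ** 2) / np.sum(
            (obs_arr - obs_arr.mean()) ** 2
        )
        assert predictive_r2(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_added_noise_degrades_expected_r2(self):
        """Independent prediction noise never helps on average."""
        deltas = []
        for seed in range(100):
            rng = np.random.default_rng(30_000 + seed)
            obs = rng.uniform(1.0, 50.0, 12)
            pred = obs * np.exp(rng.normal(0, 0.1, 12))
            noisy = pred * np.exp(rng.normal(0, 0.3, 12))
            deltas.append(predictive_r2(obs, noisy) - predictive_r2(obs, pred))
        assert np.mean(deltas) < 0


class TestTrainPredictEvaluate:
    def test_closed_loop_on_noiseless_study(self, fleet, noiseless_study):
        _, _, summaries = noiseless_study
        fit, evaluation = train_predict_evaluate(
            builtin_models()[0], fleet[:9], summaries, fleet, summaries
        )
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)
        assert evaluation.predictive_r2 == pytest.approx(1.0, abs=1e-9)
        assert evaluation.train_ids == tuple(d.device_id for d in fleet[:9])
        assert len(evaluation.eval_ids) == len(fleet)

    def test_two_step_oracle_on_noisy_study(self, fleet, noisy_study):
        """Fit with the oracle, plug in, apply the R² formula by hand."""
        from coiltox.device_model import effective_geometry
        from coiltox.scoring import model1_score

        _, _, summaries = noisy_study
        fit, evaluation = train_predict_evaluate(
            builtin_models()[0], fleet[:9], summaries, fleet, summaries
        )
        x = np.array([model1_score(*effective_geometry(d)) for d in fleet])
        y = np.array([summaries[d.device_id].mean_emission for d in fleet])
        log_fit = np.polyfit(x[:9], np.log(y[:9]), 1)
        pred = np.exp(log_fit[1]) * np.exp(log_fit[0] * x)
        expected = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert evaluation.predictive_r2 == pytest.approx(expected, rel=1e-9)

    def test_constant_score_train_fleet_errors(self):
        from coiltox.device_model import (
            AtomizerDevice, CoilSpec, CoilStyle, Orientation, WickKind, WickSpec,
        )
        from coiltox.emissions import DeviceEmissionSummary

        clones = [
            AtomizerDevice(
                f"C{i}",
                CoilSpec(CoilStyle.SINGLE, Orientation.HORIZONTAL, 100.0, 10),
                WickSpec(WickKind.MEASURED, outer_surface_area=50.0),
            )
            for i in range(3)
        ]
        summaries = {
            d.device_id: DeviceEmissionSummary(d.device_id, 10.0 + i, 1.0, 3, 0)
            for i, d in enumerate(clones)
        }
        with pytest.raises(ValueError, match="degenerate"):
            train_predict_evaluate(
                builtin_models()[0], clones, summaries, clones, summaries
            )


class TestRankModels:
    def test_single_model_ranks_first(self, fleet, noiseless_study):
        _, _, summaries = noiseless_study
        results = rank_models([builtin_models()[0]], fleet[:9], summaries, fleet, summaries)
        assert len(results) == 1 and results[0].model.name == "model1"

    def test_generating_model_outranks_power_models(self, fleet, noisy_study):
        _, _, summaries = noisy_study
        results = rank_models(builtin_models(), fleet[:9], summaries, fleet, summaries)
        assert results[0].model.name == "model1"

    def test_failures_reported_not_dropped(self, noiseless_study):
        from dataclasses import replace

        _, _, summaries = noiseless_study
        config = SyntheticConfig(seed=7)
        fleet_no_power = [
            replace(d, power=None) for d in generate_fleet(config)
        ]
        results = rank_models(
            builtin_models(), fleet_no_power[:9], summaries, fleet_no_power, summaries
        )
        by_name = {r.model.name: r for r in results}
        assert not by_name["model1"].failed
        assert by_name["power_model_1a"].failed and "W" in by_name["power_model_1a"].error
        assert results[-1].failed  # failures sort after successes

    def test_tied_models_order_by_name(self, fleet, noiseless_study):
        from coiltox.scoring import ScoreModel

        _, _, summaries = noiseless_study
        twin_b = ScoreModel("twin_b", "L/(SA*n)")
        twin_a = ScoreModel("twin_a", "L/(SA*n)")
        results = rank_models([twin_b, twin_a], fleet[:9], summaries, fleet, summaries)
        assert [r.model.name for r in results] == ["twin_a", "twin_b"]
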