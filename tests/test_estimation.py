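"""Likelihood, fitting, and variability statistics."""

import math

import numpy as np
import pytest

from hptsim import (
    FitResult,
    HormoneObservations,
    ModelParameters,
    fit_parameters,
    neg_loglik,
    parameter_cvs,
    profile_sigmas,
    scale_tsh_points,
)
from hptsim.estimation import EUTHYROID_SCALED_TSH_INDICES, SimulationDesign, predict_design
from hptsim.synth import euthyroid_dose_response_designs, synth_timecourses


def _obs(channel, times, values, weights=None):
    data = {channel: (times, values) if weights is None else (times, values, weights)}
    return HormoneObservations.from_arrays(data)


class TestNegLoglik:
    def test_single_exact_observation_unit_sigma(self):
        obs = _obs("T4", [1.0], [5.0])
        nll = neg_loglik(obs, {"T4": np.array([5.0])}, {"T4": 1.0, "T3": 1.0, "TSH": 1.0})
        assert nll == pytest.approx(math.log(2 * math.pi) / 2, abs=1e-12)

    def test_residual_equal_to_sigma_adds_half(self):
        sig = {"T4": 2.0, "T3": 1.0, "TSH": 1.0}
        exact = neg_loglik(_obs("T4", [0.0], [5.0]), {"T4": np.array([5.0])}, sig)
        off = neg_loglik(_obs("T4", [0.0], [7.0]), {"T4": np.array([5.0])}, sig)
        assert off - exact == pytest.approx(0.5, abs=1e-12)

    def test_additive_over_channels(self):
        both = HormoneObservations.from_arrays(
            {"T4": ([0.0, 1.0], [5.0, 6.0]), "T3": ([0.0], [1.2])}
        )
        preds = {"T4": np.array([5.5, 5.5]), "T3": np.array([1.0])}
        sig = {"T4": 1.3, "T3": 0.2, "TSH": 1.0}
        split = (
            neg_loglik(_obs("T4", [0.0, 1.0], [5.0, 6.0]), preds, sig)
            + neg_loglik(_obs("T3", [0.0], [1.2]), preds, sig)
        )
        assert neg_loglik(both, preds, sig) == pytest.approx(split, rel=1e-12)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            neg_loglik(_obs("T4", [0.0], [5.0]), {"T4": np.array([5.0])},
                       {"T4": 0.0, "T3": 1.0, "TSH": 1.0})


class TestSigmaProfile:
    def test_sigma_hat_is_rms_residual(self):
        values = np.array([4.0, 6.0, 5.0, 7.0])
        preds = {"T4": np.array([5.0, 5.0, 5.0, 5.0])}
        obs = _obs("T4", np.arange(4.0), values)
        sig = profile_sigmas([obs], [preds])
        assert sig["T4"] == pytest.approx(np.sqrt(np.mean((values - 5.0) ** 2)), rel=1e-12)

    def test_profiled_sigma_is_likelihood_stationary_point(self):
        values = np.array([4.0, 6.0, 5.5])
        preds = {"T4": np.array([5.0, 5.0, 5.0])}
        obs = _obs("T4", np.arange(3.0), values)
        s_hat = profile_sigmas([obs], [preds])["T4"]
        base = {"T3": 1.0, "TSH": 1.0}
        at_hat = neg_loglik(obs, preds, {"T4": s_hat, **base})
        assert at_hat < neg_loglik(obs, preds, {"T4": 1.1 * s_hat, **base})
        assert at_hat < neg_loglik(obs, preds, {"T4": 0.9 * s_hat, **base})

    def test_weights_act_as_replicates(self):
        obs_w = _obs("T4", [0.0, 1.0], [4.0, 6.0], weights=[3.0, 1.0])
        preds = {"T4": np.array([5.0, 5.0])}
        s = profile_sigmas([obs_w], [preds])["T4"]
        expected = math.sqrt((3 * 1.0 + 1 * 1.0) / 4.0)
        assert s == pytest.approx(expected, rel=1e-12)


class TestScaleTshPoints:
    @pytest.fixture()
    def tsh30(self):
        return HormoneObservations.from_arrays({"TSH": (np.arange(30.0), np.ones(30))})

    def test_factor_one_is_identity(self, tsh30):
        out = scale_tsh_points(tsh30, factor=1.0)
        assert out.frame.equals(tsh30.frame)

    def test_exactly_four_default_entries_change(self, tsh30):
        out = scale_tsh_points(tsh30)
        changed = (out.frame["weight"] != tsh30.frame["weight"]).sum()
        assert changed == len(EUTHYROID_SCALED_TSH_INDICES) == 4

    def test_composition_of_factors(self, tsh30):
        twice = scale_tsh_points(scale_tsh_points(tsh30, factor=10.0), factor=10.0)
        once = scale_tsh_points(tsh30, factor=100.0)
        assert twice.frame.equals(once.frame)

    def test_value_mode_scales_values(self, tsh30):
        out = scale_tsh_points(tsh30, indices=(0,), factor=100.0, mode="value")
        assert out.frame.loc[0, "value"] == 100.0
        assert out.frame.loc[0, "weight"] == 1.0

    def test_out_of_range_index_rejected(self, tsh30):
        with pytest.raises(IndexError):
            scale_tsh_points(tsh30, indices=(99,))


class TestFit:
    def test_no_free_parameters_returns_init(self, params):
        design = euthyroid_dose_response_designs((450.0,))[0]
        obs = synth_timecourses(params, design, np.arange(12.0, 120.0, 24.0), 0.0, seed=0)
        fit = fit_parameters([(design, obs)], init=params, free_params=())
        assert fit.estimates == {}
        assert fit.success

    def test_recovers_generating_parameters_from_noise_free_data(self, params):
        """Perturbed start recovers well-identified parameters within 1%."""
        design = euthyroid_dose_response_designs((400.0,))[0]
        times = np.arange(6.0, 120.0, 6.0)
        obs = synth_timecourses(params, design, times, 0.0, seed=0)
        init = params.replace(S4=params.S4 * 1.1, k05=params.k05 * 0.9)
        fit = fit_parameters([(design, obs)], init=init, free_params=("S4", "k05"),
                             n_restarts=1, maxiter=250)
        assert fit.success
        assert fit.estimates["S4"] == pytest.approx(params.S4, rel=0.01)
        assert fit.estimates["k05"] == pytest.approx(params.k05, rel=0.01)

    def test_deterministic_given_seed(self, params):
        design = euthyroid_dose_response_designs((450.0,))[0]
        obs = synth_timecourses(params, design, np.arange(12.0, 120.0, 12.0), 0.0, seed=0)
        init = params.replace(S4=params.S4 * 1.05)
        kw = dict(init=init, free_params=("S4",), n_restarts=2, seed=7, maxiter=40)
        f1 = fit_parameters([(design, obs)], **kw)
        f2 = fit_parameters([(design, obs)], **kw)
        assert f1.estimates == f2.estimates and f1.nll == f2.nll

    def test_unknown_free_parameter_rejected(self, params):
        with pytest.raises(ValueError):
            fit_parameters([], init=params, free_params=("nope",))


class TestParameterCvs:
    def test_quadratic_oracle(self):
        """A quadratic objective with known curvature gives %CV = 100 s / |theta|."""
        theta, s = 2.0, 0.3
        fit = FitResult(estimates={"S4": theta}, sigmas={}, nll=0.0, success=True,
                        n_evaluations=1, n_restarts=0)
        cv = parameter_cvs(fit, objective=lambda x: ((x[0] - theta) / s) ** 2 / 2.0)
        assert cv["S4"] == pytest.approx(100.0 * s / theta, rel=1e-4)

    def test_flat_direction_reported_missing(self):
        fit = FitResult(estimates={"S4": 2.0, "k05": 1.0}, sigmas={}, nll=0.0,
                        success=True, n_evaluations=1, n_restarts=0)
        with pytest.warns(UserWarning):
            cv = parameter_cvs(fit, objective=lambda x: (x[0] - 2.0) ** 2 / 2.0)
        assert math.isnan(cv["k05"])

    def test_noisier_data_doubles_cv(self, params):
        """Hessian %CVs scale linearly with the observation noise level."""
        design = euthyroid_dose_response_designs((400.0,))[0]
        times = np.arange(6.0, 120.0, 6.0)
        fit = FitResult(estimates={"S4": params.S4}, sigmas={}, nll=0.0, success=True,
                        n_evaluations=1, n_restarts=0)
        cvs = []
        for scale in (1.0, 2.0):
            sig = {"T4": 2.0 * scale, "T3": 0.05 * scale, "TSH": 0.1 * scale}
            obs = synth_timecourses(params, design, times, sig, seed=11)
            cvs.append(parameter_cvs(fit, [(design, obs)], base=params)["S4"])
        assert cvs[1] / cvs[0] == pytest.approx(2.0, rel=0.35)


class TestPredictDesign:
    def test_predictions_at_observation_times(self, params):
        design = euthyroid_dose_response_designs((600.0,))[0]
        obs = HormoneObservations.from_arrays({"T4": ([0.0, 30.0], [0.0, 0.0])})
        preds = predict_design(params, design, obs)
        # pre-dose value is euthyroid; post-dose T4 is elevated
        assert preds["T4"][1] > preds["T4"][0] * 1.2

    def test_personalized_design(self, params, ref_female):
        design = SimulationDesign(events=((0.0, 0.0, 30.0),), duration_h=8.0,
                                  patient=ref_female, rtf=0.0)
        obs = HormoneObservations.from_arrays({"T3": ([1.0, 4.0], [0.0, 0.0])})
        preds = predict_design(params, design, obs)
        assert np.all(preds["T3"] > 0)
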