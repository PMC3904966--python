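"""Correlation model, curve averaging, and weighted fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intrachain.fcs import (CalibrationError, CorrelationCurve, FCSModel,
                            FCSModelParams, FCSParameterError, average_curves,
                            calibrate_s, fit_curve, model_g)
from intrachain.simulate import multi_tau_lag_grid, simulate_fcs_curve

LAGS = multi_tau_lag_grid()


def make_curve(params, variance=1e-6):
    g = model_g(params, LAGS)
    return CorrelationCurve(LAGS, g, np.full_like(LAGS, variance))


class TestModelG:
    def test_zero_lag_limits(self):
        pure = FCSModelParams(1.0, 4e-4)
        assert model_g(pure, 1e-12) == pytest.approx(1.0, rel=1e-6)
        kinetic = FCSModelParams(2.0, 4e-4, kinetic_terms=[(0.3, 1e-6)])
        assert model_g(kinetic, 1e-12) == pytest.approx(0.65, rel=1e-6)

    def test_closed_form_at_diffusion_time(self):
        params = FCSModelParams(1.0, 4e-4, s=0.175)
        expected = 0.5 * (1 + 0.175 ** 2) ** -0.5
        assert model_g(params, 4e-4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4925, abs=5e-5)

    def test_long_lag_decay_to_zero(self):
        params = FCSModelParams(1.0, 4e-4, kinetic_terms=[(0.5, 1e-6)])
        assert model_g(params, 1e3) < 1e-4

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.2, 10), st.floats(1e-5, 1e-2), st.floats(0, 2),
           st.floats(1e-7, 1e-5), st.floats(0.05, 1.0))
    def test_strictly_decreasing(self, n, tau_d, amp, tau_r, s):
        params = FCSModelParams(n, tau_d, s, [(amp, tau_r)] if amp else [])
        g = model_g(params, np.geomspace(1e-8, 1.0, 120))
        assert np.all(np.diff(g) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(FCSParameterError):
            FCSModelParams(-1.0, 4e-4)
        with pytest.raises(FCSParameterError):
            FCSModelParams(1.0, 4e-4, kinetic_terms=[(0.3, -1e-6)])


class TestAveraging:
    def test_identical_curves(self):
        params = FCSModelParams(1.5, 3e-4)
        curve = make_curve(params, 0.0)
        avg = average_curves([curve, curve])
        assert np.allclose(avg.g, curve.g)
        assert np.all(avg.variance == 0)
        assert avg.n_acquisitions == 2

    def test_two_point_sample_variance(self):
        g = model_g(FCSModelParams(1.0, 3e-4), LAGS)
        up = CorrelationCurve(LAGS, g, np.zeros_like(g))
        down = CorrelationCurve(LAGS, -g, np.zeros_like(g))
        avg = average_curves([up, down])
        assert np.allclose(avg.g, 0.0)
        assert np.allclose(avg.variance, 2 * g ** 2)  # ddof=1 for two points

    def test_mismatched_grids_rejected(self):
        a = make_curve(FCSModelParams(1.0, 3e-4))
        b = CorrelationCurve(LAGS * 2, a.g, a.variance)
        with pytest.raises(ValueError, match="lag grid"):
            average_curves([a, b])

    def test_seeded_replicates_average_near_model(self):
        params = FCSModelParams(2.0, 4e-4, kinetic_terms=[(0.3, 1.2e-6)])
        curves = simulate_fcs_curve(params, noise_level=0.02, n_replicates=10, seed=3)
        avg = average_curves(curves)
        true = model_g(params, avg.lags)
        se = np.sqrt(avg.variance / avg.n_acquisitions)
        assert np.all(np.abs(avg.g - true) <= 3.5 * se + 1e-12)


class TestFitting:
    def test_noiseless_self_consistency(self):
        true = FCSModelParams(2.0, 4e-4, 0.175, [(0.3, 1.2e-6)])
        result = fit_curve(make_curve(true), 1, s_fixed=0.175)
        assert result.converged
        assert result.params.N == pytest.approx(2.0, rel=1e-3)
        assert result.params.tau_d == pytest.approx(4e-4, rel=1e-3)
        amp, tau_r = result.params.kinetic_terms[0]
        assert amp == pytest.approx(0.3, rel=1e-3)
        assert tau_r == pytest.approx(1.2e-6, rel=1e-3)

    def test_uniform_variance_equals_unit_weights(self):
        true = FCSModelParams(1.0, 3e-4, 0.175, [(0.4, 2e-6)])
        g = model_g(true, LAGS)
        rng = np.random.default_rng(7)
        noisy = g + rng.normal(0, 0.004, size=g.size)
        res_a = fit_curve(CorrelationCurve(LAGS, noisy, np.full_like(g, 2.5)), 1)
        with pytest.warns(UserWarning, match="unit weights"):
            res_b = fit_curve(CorrelationCurve(LAGS, noisy, np.zeros_like(g)), 1)
        assert res_a.params.tau_d == pytest.approx(res_b.params.tau_d, rel=1e-6)
        assert res_a.params.kinetic_terms[0][1] == \
            pytest.approx(res_b.params.kinetic_terms[0][1], rel=1e-6)

    def test_extra_component_never_hurts_r_squared(self):
        true = FCSModelParams(2.0, 4e-4, 0.175, [(0.3, 1.2e-6)])
        curves = simulate_fcs_curve(true, noise_level=0.01, n_replicates=6, seed=11)
        avg = average_curves(curves)
        one = fit_curve(avg, 1)
        two = fit_curve(avg, 2, initial_guess={
            "a1": one.params.kinetic_terms[0][0],
            "tau_r1": one.params.kinetic_terms[0][1],
            "a2": 0.01, "tau_r2": 1e-5,
        })
        assert two.r_squared >= one.r_squared - 1e-9

    def test_second_component_leaves_kinetics_unchanged(self):
        # refitting a one-component curve with two components should give a
        # negligible R^2 gain and the same relaxation time
        true = FCSModelParams(2.0, 4e-4, 0.175, [(0.3, 1.2e-6)])
        curves = simulate_fcs_curve(true, noise_level=0.01, n_replicates=10, seed=5)
        avg = average_curves(curves)
        one = fit_curve(avg, 1)
        two = fit_curve(avg, 2, initial_guess={
            "a1": one.params.kinetic_terms[0][0],
            "tau_r1": one.params.kinetic_terms[0][1],
            "a2": 0.02, "tau_r2": 1e-5,
        })
        assert two.r_squared - one.r_squared < 1e-3
        dominant_tau = two.tau_r
        sigma = one.uncertainties.get("tau_r1")
        tol = 3 * sigma if sigma and np.isfinite(sigma) else 0.1 * one.tau_r
        assert abs(dominant_tau - one.tau_r) <= tol

    def test_quenched_fraction_mapping(self):
        params = FCSModelParams(1.0, 4e-4, kinetic_terms=[(0.5, 1e-6)])
        assert params.quenched_fractions[0] == pytest.approx(1 / 3)


class TestCalibration:
    @pytest.mark.parametrize("true_s", [0.175, 0.2])
    def test_recovers_volume_ratio(self, true_s):
        params = FCSModelParams(0.8, 5e-5, s=true_s)
        curves = simulate_fcs_curve(params, noise_level=0.005, n_replicates=10, seed=2)
        s, result = calibrate_s(average_curves(curves))
        assert result.converged
        assert s == pytest.approx(true_s, abs=0.005)

    def test_two_species_input_flagged(self):
        fast = model_g(FCSModelParams(2.0, 5e-5), LAGS)
        slow = model_g(FCSModelParams(2.0, 5e-3), LAGS)
        mixture = 0.5 * (fast + slow)
        curve = CorrelationCurve(LAGS, mixture, np.full_like(mixture, 1e-8))
        with pytest.warns(UserWarning, match="more than one diffusing species"):
            calibrate_s(curve)
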