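"""Stejskal-Tanner forward model and decay fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcdosy import (
    AcquisitionParams,
    DecayCurve,
    FitConvergenceError,
    b_factor,
    bootstrap_expanded_uncertainty,
    fit_biexponential,
    fit_monoexponential,
    predict_intensity,
)


class TestBFactor:
    def test_zero_gradient_gives_zero(self, acq):
        assert b_factor(acq, 0.0) == 0.0

    def test_quadratic_in_gradient(self, acq):
        assert b_factor(acq, 0.6) == pytest.approx(4.0 * b_factor(acq, 0.3), rel=1e-12)

    def test_hand_computed_value(self, acq):
        # gamma=2.675e8, delta=1.5 ms, Delta=0.1 s, g=0.3 T/m
        assert b_factor(acq, 0.3) == pytest.approx(1.442e9, rel=1e-3)

    def test_negative_gradient_rejected(self, acq):
        with pytest.raises(ValueError):
            b_factor(acq, -0.1)


class TestAcquisitionParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionParams(little_delta=-1e-3)
        with pytest.raises(ValueError):
            AcquisitionParams(little_delta=0.3, big_delta=0.05)

    def test_bipolar_doubles_effective_delta(self):
        a = AcquisitionParams.from_bipolar(0.75e-3, 0.1)
        assert a.little_delta == pytest.approx(1.5e-3)


class TestPredictIntensity:
    def test_no_diffusion_no_attenuation(self, acq):
        assert predict_intensity(2.0, 0.0, acq, 0.4) == pytest.approx(2.0)

    def test_hand_computed_attenuation(self, acq):
        # b*D = 0.7209 at g=0.3, D=5e-10
        assert predict_intensity(1.0, 5e-10, acq, 0.3) == pytest.approx(0.4863, abs=5e-4)

    def test_negative_D_rejected(self, acq):
        with pytest.raises(ValueError):
            predict_intensity(1.0, -1e-10, acq, 0.1)

    def test_strictly_decreasing_in_g(self, acq, ramp16):
        I = predict_intensity(1.0, 3e-10, acq, ramp16)
        assert np.all(np.diff(I) < 0)


class TestDecayCurve:
    def test_sorts_by_gradient(self):
        c = DecayCurve([0.3, 0.1, 0.2], [1.0, 3.0, 2.0])
        assert list(c.gradient_strengths) == [0.1, 0.2, 0.3]
        assert list(c.intensities) == [3.0, 2.0, 1.0]

    def test_rejects_duplicates_and_negatives(self):
        with pytest.raises(ValueError):
            DecayCurve([0.1, 0.1], [1.0, 2.0])
        with pytest.raises(ValueError):
            DecayCurve([-0.1, 0.2], [1.0, 2.0])


class TestMonoexponentialFit:
    def test_noiseless_recovery(self, acq, ramp16):
        D = 5e-10
        curve = DecayCurve(ramp16, predict_intensity(1.0, D, acq, ramp16))
        fit = fit_monoexponential(curve, acq)
        assert fit.D[0] == pytest.approx(D, abs=1e-13)
        assert fit.I0 == pytest.approx(1.0, rel=1e-8)

    def test_constant_intensities_signal_boundary(self, acq, ramp16):
        curve = DecayCurve(ramp16, np.ones(16))
        with pytest.raises(FitConvergenceError):
            fit_monoexponential(curve, acq)

    @pytest.mark.parametrize("scale", [0.5, 7.3, 1e6])
    def test_D_invariant_to_intensity_rescaling(self, acq, ramp16, scale):
        rng = np.random.default_rng(11)
        I = predict_intensity(1.0, 3e-10, acq, ramp16) + rng.normal(0, 0.01, 16)
        base = fit_monoexponential(DecayCurve(ramp16, I), acq)
        scaled = fit_monoexponential(DecayCurve(ramp16, scale * I), acq)
        assert scaled.D[0] == pytest.approx(base.D[0], rel=1e-9)
        assert scaled.I0 == pytest.approx(scale * base.I0, rel=1e-9)

    def test_nonpositive_intensities_excluded_from_init(self, acq, ramp16):
        I = predict_intensity(1.0, 8e-10, acq, ramp16)
        I[-1] = -1e-4  # noise pushed the weakest point below zero
        fit = fit_monoexponential(DecayCurve(ramp16, I), acq)
        assert fit.n_excluded_points == 1
        assert fit.D[0] == pytest.approx(8e-10, rel=0.05)

    @settings(max_examples=25, deadline=None)
    @given(
        log10_D=st.floats(min_value=-11.0, max_value=-9.0),
        I0=st.floats(min_value=0.1, max_value=1e4),
    )
    def test_round_trip_any_theta(self, log10_D, I0):
        # fit(predict(theta)) = theta for noiseless input
        acq = AcquisitionParams(gamma=2.675e8, little_delta=1.5e-3, big_delta=0.1)
        ramp = np.linspace(0.02, 0.5, 16)
        D = 10.0**log10_D
        fit = fit_monoexponential(DecayCurve(ramp, predict_intensity(I0, D, acq, ramp)), acq)
        assert fit.D[0] == pytest.approx(D, rel=1e-6)
        assert fit.I0 == pytest.approx(I0, rel=1e-6)


class TestBiexponentialFit:
    def _curve(self, acq, ramp, D1, D2, w, noise=0.0, seed=0):
        b = b_factor(acq, ramp)
        I = w * np.exp(-b * D1) + (1 - w) * np.exp(-b * D2)
        if noise:
            I = I + np.random.default_rng(seed).normal(0, noise, ramp.size)
        return DecayCurve(ramp, I)

    def test_noiseless_two_component_recovery(self, acq, ramp24):
        fit = fit_biexponential(self._curve(acq, ramp24, 5e-10, 5e-11, 0.5), acq)
        assert fit.model == "biexponential"
        assert fit.D[0] == pytest.approx(5e-10, rel=0.01)
        assert fit.D[1] == pytest.approx(5e-11, rel=0.01)
        assert fit.component_weights[0] == pytest.approx(0.5, abs=0.01)

    def test_components_sorted_descending(self, acq, ramp24):
        fit = fit_biexponential(self._curve(acq, ramp24, 1e-10, 7e-10, 0.3), acq)
        assert fit.D[0] > fit.D[1]

    def test_equal_components_collapse_to_mono(self, acq, ramp24):
        fit = fit_biexponential(self._curve(acq, ramp24, 3e-10, 3e-10, 0.5), acq)
        assert fit.model == "monoexponential"
        assert fit.D[0] == pytest.approx(3e-10, rel=1e-6)

    def test_mono_data_selects_mono(self, acq, ramp24):
        # 1% noise on a genuinely single-component decay must not grow a
        # second component
        curve = self._curve(acq, ramp24, 4e-10, 4e-10, 1.0, noise=0.01, seed=3)
        fit = fit_biexponential(curve, acq)
        assert fit.model == "monoexponential"


class TestBootstrapUncertainty:
    def test_noiseless_curve_near_zero(self, acq, ramp16):
        curve = DecayCurve(ramp16, predict_intensity(1.0, 4e-10, acq, ramp16))
        fit = fit_monoexponential(curve, acq)
        pct = bootstrap_expanded_uncertainty(curve, acq, fit, B=100, k=2.0, seed=1)
        assert pct == pytest.approx(0.0, abs=1e-6)

    def test_linear_in_coverage_factor(self, acq, ramp16):
        rng = np.random.default_rng(5)
        I = predict_intensity(1.0, 4e-10, acq, ramp16) + rng.normal(0, 0.01, 16)
        curve = DecayCurve(ramp16, I)
        fit = fit_monoexponential(curve, acq)
        u1 = bootstrap_expanded_uncertainty(curve, acq, fit, B=150, k=1.0, seed=7)
        u2 = bootstrap_expanded_uncertainty(curve, acq, fit, B=150, k=2.0, seed=7)
        assert u2 == pytest.approx(2.0 * u1, rel=1e-12)

    def test_too_few_replicates_rejected(self, acq, ramp16):
        curve = DecayCurve(ramp16, predict_intensity(1.0, 4e-10, acq, ramp16))
        fit = fit_monoexponential(curve, acq)
        with pytest.raises(ValueError):
            bootstrap_expanded_uncertainty(curve, acq, fit, B=50)

    def test_noise_increases_uncertainty(self, acq, ramp16):
        # expanded uncertainty grows with the noise level (averaged over seeds)
        clean = predict_intensity(1.0, 4e-10, acq, ramp16)
        med = {}
        for noise in (0.005, 0.03):
            vals = []
            for seed in range(10):
                I = clean + np.random.default_rng(seed).normal(0, noise, 16)
                curve = DecayCurve(ramp16, I)
                fit = fit_monoexponential(curve, acq)
                vals.append(bootstrap_expanded_uncertainty(curve, acq, fit, B=100, seed=seed))
            med[noise] = np.median(vals)
        assert med[0.03] > med[0.005]
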