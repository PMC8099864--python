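"""Anisotropy arithmetic, corrections, rotational-correlation fitting and angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faded.anisotropy import (
    CorrectionFactors,
    PolarizedSignal,
    RotationalDiffusionModel,
    angle_from_fundamental,
    anisotropy_decay,
    compensate_bleed_through,
    estimate_g_factor,
    estimate_na_correction,
    fit_rotational_correlation,
    fundamental_from_angle,
    perrin_fundamental,
    perrin_steady,
    steady_state_anisotropy,
)
from faded.simulate import SimulationConfig, make_polarized_pair
from faded.tcspc import DecayHistogram, MultiExpModel

MICROSCOPE = dict(n_channels=3125, dwell=0.016, counts_peak=100_000)


class TestSteadyState:
    def test_equal_channels_give_zero(self):
        assert steady_state_anisotropy(PolarizedSignal(100, 100)) == 0.0

    def test_hand_arithmetic(self):
        assert steady_state_anisotropy(PolarizedSignal(200, 100)) == pytest.approx(0.25)

    def test_theoretical_maximum(self):
        assert steady_state_anisotropy(PolarizedSignal(500, 0)) == 1.0

    def test_corrections_applied(self):
        r = steady_state_anisotropy(
            PolarizedSignal(200, 100), CorrectionFactors(G=1.1, f_corr=1.2)
        )
        assert r == pytest.approx(1.2 * (200 - 110) / (200 + 220))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            steady_state_anisotropy(PolarizedSignal(0, 0))

    @settings(derandomize=True, max_examples=200)
    @given(
        ipar=st.floats(0, 1e6),
        iperp=st.floats(0, 1e6),
    )
    def test_bounds_property(self, ipar, iperp):
        # r in [-0.5, 1] for all non-negative intensities at G = f_corr = 1;
        # the lower bound is attained only at I_par = 0
        if ipar + 2 * iperp <= 0:
            return
        r = steady_state_anisotropy(PolarizedSignal(ipar, iperp))
        # the -0.5 bound is reached only as I_par/I_perp -> 0 (float-exactly
        # for I_par below machine epsilon relative to I_perp)
        assert -0.5 <= r <= 1.0


class TestInstrumentCorrections:
    def test_g_factor_equal_channels(self):
        assert estimate_g_factor(500, 500) == 1.0

    def test_g_factor_hand_arithmetic(self):
        assert estimate_g_factor(1100, 1000) == pytest.approx(1.1)

    def test_g_factor_self_consistency(self):
        g = estimate_g_factor(1100, 1000)
        r = steady_state_anisotropy(PolarizedSignal(1100, 1000), CorrectionFactors(G=g))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_na_correction(self):
        assert estimate_na_correction(0.35, 0.35) == 1.0
        assert estimate_na_correction(0.35, 0.30) == pytest.approx(1.1667, abs=1e-4)
        assert estimate_na_correction(-0.35, -0.30) == pytest.approx(1.1667, abs=1e-4)

    def test_na_correction_zero_observed(self):
        with pytest.raises(ValueError):
            estimate_na_correction(0.35, 0.0)


class TestAnisotropyDecay:
    def test_equal_channels_give_zero_trace(self):
        counts = np.full(200, 1000.0)
        pair = [DecayHistogram(counts=counts, dwell=0.1) for _ in range(2)]
        ad = anisotropy_decay(*pair)
        np.testing.assert_allclose(ad.r[ad.mask], 0.0)

    def test_zero_channels_masked(self):
        counts = np.concatenate([np.full(50, 1000.0), np.zeros(50)])
        d = DecayHistogram(counts=counts, dwell=0.1)
        ad = anisotropy_decay(d, d)
        assert not ad.mask[60]
        assert np.isnan(ad.r[60])

    def test_recovery_within_propagated_error(self):
        # simulated pair from r(t) = 0.35 exp(-t/34): the trace must agree with
        # the generating curve within its shot-noise error bars for ~95% of channels
        cfg = SimulationConfig(seed=42, **MICROSCOPE)
        model = MultiExpModel((1.0,), (3.1,))
        par, perp = make_polarized_pair(model, 0.35, 34.0, cfg)
        ad = anisotropy_decay(par, perp, min_total=100.0)
        t0 = cfg.t0
        sel = ad.mask & (ad.time > t0 + 1.0)
        # the depolarisation clock starts at the excitation pulse (t0)
        truth = 0.35 * np.exp(-(ad.time[sel] - t0) / 34.0)
        frac = np.mean(np.abs(ad.r[sel] - truth) < 2 * ad.sigma_r[sel])
        assert frac >= 0.93

    def test_grid_mismatch_rejected(self):
        a = DecayHistogram(counts=np.ones(100), dwell=0.1)
        b = DecayHistogram(counts=np.ones(50), dwell=0.1)
        with pytest.raises(ValueError):
            anisotropy_decay(a, b)


class TestRotationalCorrelation:
    def _pair(self, r0, theta, seed):
        cfg = SimulationConfig(seed=seed, **MICROSCOPE)
        model = MultiExpModel((1.0,), (3.1,))
        return make_polarized_pair(model, r0, theta, cfg), cfg

    @pytest.mark.parametrize("theta,r0", [(34.0, 0.153), (28.0, 0.11)])
    def test_theta_recovery(self, theta, r0):
        (par, perp), cfg = self._pair(r0, theta, seed=int(theta * 10))
        ad = anisotropy_decay(par, perp)
        _, theta_hat = fit_rotational_correlation(ad, t_start=cfg.t0 + 5.0)
        assert theta_hat == pytest.approx(theta, rel=0.10)

    def test_flat_trace_reports_no_decay(self):
        t = np.arange(2000) * 0.016
        ad_counts = np.full(2000, 1e5)
        par = DecayHistogram(counts=ad_counts * (1 + 2 * 0.2) / 3, dwell=0.016)
        perp = DecayHistogram(counts=ad_counts * (1 - 0.2) / 3, dwell=0.016)
        ad = anisotropy_decay(par, perp)
        with pytest.warns(UserWarning):
            res = RotationalDiffusionModel(ad, t_start=5.0).fit()
        assert res.no_decay_detected
        assert res.r_amplitude == pytest.approx(0.2, abs=0.01)

    def test_insufficient_channels_rejected(self):
        par = DecayHistogram(counts=np.full(30, 1000.0), dwell=1.0)
        ad = anisotropy_decay(par, par)
        with pytest.raises(ValueError):
            RotationalDiffusionModel(ad, t_start=25.0)


class TestPerrin:
    @pytest.mark.parametrize(
        "r,tau,theta,r0",
        [
            (0.14, 3.1, 34.0, 0.153),
            (0.10, 3.0, 28.0, 0.111),
            (-0.068, 3.0, 33.0, -0.0742),
            (-0.03, 3.02, 33.0, -0.033),
        ],
    )
    def test_fundamental_worked_values(self, r, tau, theta, r0):
        assert perrin_fundamental(r, tau, theta) == pytest.approx(r0, abs=5e-4)

    def test_no_rotation_limit(self):
        assert perrin_fundamental(0.2, 3.0, 1e12) == pytest.approx(0.2)

    def test_depolarization_factor_92_percent(self):
        assert perrin_steady(1.0, 3.1, 34.0) == pytest.approx(0.916, abs=5e-3)

    def test_bound_state_steady_value(self):
        assert perrin_steady(-0.033, 3.0, 33.0) == pytest.approx(-0.030, abs=5e-4)

    @settings(derandomize=True)
    @given(
        r0=st.floats(-0.2, 0.4),
        tau=st.floats(0.01, 100),
        theta=st.floats(0.01, 1e4),
    )
    def test_round_trip_property(self, r0, tau, theta):
        r = perrin_steady(r0, tau, theta)
        assert perrin_fundamental(r, tau, theta) == pytest.approx(r0, abs=1e-12)

    def test_monotone_in_theta(self):
        thetas = np.linspace(1.0, 100.0, 50)
        up = [perrin_steady(0.3, 3.0, th) for th in thetas]
        down = [perrin_steady(-0.1, 3.0, th) for th in thetas]
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)


class TestBleedThroughCompensation:
    def test_calcium_free_worked_value(self):
        assert compensate_bleed_through(0.10, 0.35, 0.20) == pytest.approx(0.0375, abs=5e-4)

    def test_calcium_bound_worked_value(self):
        assert compensate_bleed_through(-0.03, 0.35, 0.09) == pytest.approx(-0.0676, abs=5e-4)

    def test_zero_fraction_is_identity(self):
        assert compensate_bleed_through(0.123, 0.35, 0.0) == 0.123

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            compensate_bleed_through(0.1, 0.35, 1.0)

    @settings(derandomize=True, max_examples=300)
    @given(
        r_d=st.floats(-0.2, 0.4),
        r_a=st.floats(-0.2, 0.4),
        f_d=st.floats(0.0, 0.95),
    )
    def test_exact_inverse_of_intensity_mixing(self, r_d, r_a, f_d):
        # forward mixing r_obs = r_d f_d + r_a (1 - f_d), then compensation
        r_obs = r_d * f_d + r_a * (1 - f_d)
        assert compensate_bleed_through(r_obs, r_d, f_d) == pytest.approx(r_a, abs=1e-12)


class TestDipoleAngle:
    @pytest.mark.parametrize(
        "r0,beta",
        [
            (0.4, 0.0),
            (-0.2, 90.0),
            (0.0, 54.7356),
            (-0.074, 62.7),
            (0.15, 40.2),
        ],
    )
    def test_angle_worked_values(self, r0, beta):
        assert angle_from_fundamental(r0) == pytest.approx(beta, abs=0.05)

    def test_reported_displacement_rounds_to_40_degrees(self):
        assert round(angle_from_fundamental(0.153)) == 40

    def test_forward_values(self):
        assert fundamental_from_angle(0.0) == pytest.approx(0.4)
        assert fundamental_from_angle(54.7356) == pytest.approx(0.0, abs=1e-6)
        assert fundamental_from_angle(62.7) == pytest.approx(-0.074, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            angle_from_fundamental(0.41)
        with pytest.raises(ValueError):
            fundamental_from_angle(95.0)

    @settings(derandomize=True)
    @given(beta=st.floats(0.0, 90.0))
    def test_inverse_identity_property(self, beta):
        tol = 1e-9 if 0.01 <= beta <= 89.99 else 1e-5
        assert angle_from_fundamental(fundamental_from_angle(beta)) == pytest.approx(
            beta, abs=tol
        )
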