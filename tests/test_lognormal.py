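import numpy as np
import pytest

from turnsig.lognormal import (
    CharacteristicPoints,
    ExtractionError,
    LognormalComponent,
    TurnSignatureModel,
    derived_timing,
    estimate_mu_t0_D,
    estimate_sigma,
    find_characteristic_points,
    fit_two_phase,
    lognormal_value,
    snr,
)

SQ2PI = np.sqrt(2 * np.pi)


def sample_component(c, fs=600.0, t_end=None, t_start=0.0):
    if t_end is None:
        t_end = c.t0 + np.exp(c.mu + 4 * c.sigma)
    t = np.arange(t_start, t_end, 1.0 / fs)
    return t, lognormal_value(t, c)


class TestLognormalValue:
    def test_zero_before_onset(self):
        c = LognormalComponent(10.0, 0.5, 0.0, 0.3)
        assert lognormal_value(0.5, c) == 0.0
        assert lognormal_value(-1.0, c) == 0.0

    def test_standard_value_at_one(self):
        c = LognormalComponent(1.0, 0.0, 0.0, 1.0)
        assert lognormal_value(1.0, c) == pytest.approx(1.0 / SQ2PI, rel=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 0.5), (-0.4, 0.25), (0.3, 0.8)])
    def test_argmax_location(self, mu, sigma):
        # numeric maximization oracle for the mode at t0 + e^(mu - sigma^2)
        c = LognormalComponent(5.0, 0.2, mu, sigma)
        t, v = sample_component(c, fs=5000)
        assert t[np.argmax(v)] == pytest.approx(
            0.2 + np.exp(mu - sigma**2), abs=1e-3
        )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            LognormalComponent(1.0, 0.0, 0.0, -0.1)

    @pytest.mark.parametrize("D", [5.0, 25.0, 60.0])
    def test_area_equals_command_amplitude(self, D):
        c = LognormalComponent(D, 0.1, -0.2, 0.4)
        t, v = sample_component(c, fs=1000)
        assert np.trapezoid(v, t) == pytest.approx(D, rel=5e-3)

    def test_vmax_matches_fine_grid_peak(self):
        c = LognormalComponent(30.0, 0.0, -0.1, 0.35)
        t, v = sample_component(c, fs=20000)
        assert v.max() == pytest.approx(c.vmax, rel=1e-3)


class TestDerivedTiming:
    def test_closed_forms_match_numeric_moments(self):
        c = LognormalComponent(1.0, 0.0, 0.0, 0.5)
        tbar, s_resp = derived_timing(c)
        assert tbar == pytest.approx(np.exp(0.125), rel=1e-9)
        assert s_resp == pytest.approx(np.exp(0.125) * np.sqrt(np.exp(0.25) - 1), rel=1e-9)
        # numeric first/second moment oracle
        t = np.arange(1e-6, 60, 1e-4)
        lam = lognormal_value(t, c)
        m1 = np.trapezoid(t * lam, t)
        m2 = np.trapezoid((t - m1) ** 2 * lam, t)
        assert tbar == pytest.approx(m1, rel=5e-3)
        assert s_resp == pytest.approx(np.sqrt(m2), rel=5e-3)

    def test_translation_invariance(self):
        c = LognormalComponent(1.0, 0.0, 0.0, 0.5)
        shifted = c.shifted(1.0)
        assert shifted.tbar == pytest.approx(c.tbar + 1.0)
        assert shifted.s_resp == pytest.approx(c.s_resp)


class TestCharacteristicPoints:
    def test_exact_lognormal_point_locations(self):
        # closed-form mode/inflections for sigma=0.5, mu=0, verified by
        # numeric root-finding on the analytic curve
        c = LognormalComponent(25.0, 0.0, 0.0, 0.5)
        t, v = sample_component(c, fs=600)
        p = find_characteristic_points(v, t)
        assert p.tP3 == pytest.approx(np.exp(-0.25), abs=1e-3)
        a = 0.5 * np.sqrt(0.25 * 0.25 + 1)
        assert p.tP2 == pytest.approx(np.exp(-0.375 - a), abs=2e-3)  # 0.41050
        assert p.tP4 == pytest.approx(np.exp(-0.375 + a), abs=2e-3)  # 1.15072
        assert p.vP3 == pytest.approx(c.vmax, rel=1e-3)

    def test_symmetric_lobe_symmetric_points(self):
        t = np.linspace(0, 2, 600)
        v = np.exp(-0.5 * ((t - 1.0) / 0.2) ** 2)
        p = find_characteristic_points(v, t)
        assert p.tP3 == pytest.approx(1.0, abs=1e-6)
        assert (p.tP3 - p.tP2) == pytest.approx(p.tP4 - p.tP3, rel=1e-3)

    def test_monotone_ramp_fails(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ExtractionError):
            find_characteristic_points(t.copy(), t)

    def test_out_of_order_points_rejected(self):
        with pytest.raises(ExtractionError):
            CharacteristicPoints(0.5, 0.2, 0.8, 1.2, 2.0, 10.0)


class TestSigmaEstimation:
    def test_log3sigma_convention_frozen_example(self):
        # points at the e^(mu -/+ 3 sigma) convention for sigma=0.5, mu=0
        p = CharacteristicPoints(
            np.exp(-1.5), 0.41050, np.exp(-0.25), 1.15072, np.exp(1.5), 1.0
        )
        ratio = (p.tP3 - p.tP1) / (p.tP5 - p.tP1)
        assert ratio == pytest.approx(0.13049, abs=1e-5)
        assert estimate_sigma(p, convention="log3sigma") == pytest.approx(0.5, abs=1e-6)

    def test_threshold_convention_round_trip(self):
        for sigma in (0.15, 0.3, 0.6):
            c = LognormalComponent(20.0, 0.3, -0.2, sigma)
            t, v = sample_component(c, fs=2000)
            p = find_characteristic_points(v, t)
            assert estimate_sigma(p, "threshold") == pytest.approx(sigma, rel=1e-3)

    def test_degenerate_ratio_fails(self):
        p = CharacteristicPoints(0.0, 0.4, 0.5, 0.6, 1.0, 1.0)
        # ratio 0.5 -> would need sigma <= 0 under the threshold convention
        with pytest.raises(ExtractionError):
            estimate_sigma(p, "threshold")

    def test_log3sigma_rhs_monotone(self):
        # dense-grid scan: unique root guaranteed by monotonicity
        s = np.linspace(0.01, 3.0, 500)
        rhs = (np.exp(-(s**2)) - np.exp(-3 * s)) / (np.exp(3 * s) - np.exp(-3 * s))
        assert np.all(np.diff(rhs) < 0)


class TestMuT0DEstimation:
    def test_forward_simulate_invert(self):
        c = LognormalComponent(25.0, 0.2, -0.1, 0.35)
        t, v = sample_component(c, fs=600)
        p = find_characteristic_points(v, t)
        sigma = estimate_sigma(p, "threshold")
        mu, t0, D = estimate_mu_t0_D(p, sigma)
        assert mu == pytest.approx(-0.1, abs=5e-3)
        assert t0 == pytest.approx(0.2, abs=5e-3)
        assert D == pytest.approx(25.0, rel=5e-3)

    def test_peak_height_identity(self):
        # vP3 = e^(0.125)/(0.5 sqrt(2 pi)) with sigma=0.5, mu=0 -> D = 1
        vP3 = np.exp(0.125) / (0.5 * SQ2PI)
        p = CharacteristicPoints(0.1, 0.41050, np.exp(-0.25), 1.15072, 4.0, vP3)
        mu, t0, D = estimate_mu_t0_D(p, 0.5, check_consistency=False)
        assert D == pytest.approx(1.0, abs=1e-4)
        assert t0 == pytest.approx(0.0, abs=1e-4)

    def test_inverted_inflections_fail(self):
        bad = CharacteristicPoints(0.1, 0.4, 0.6, 1.1, 2.0, 1.0)
        object.__setattr__(bad, "tP4", 0.3)  # bypass ordering validation
        with pytest.raises(ExtractionError):
            estimate_mu_t0_D(bad, 0.4)


class TestSnr:
    def test_perfect_reconstruction_capped(self):
        t = np.linspace(0, 1, 100)
        v = np.sin(np.pi * t)
        assert snr(v, v, t) == 100.0

    def test_zero_reconstruction_is_zero_db(self):
        t = np.linspace(0, 1, 100)
        v = np.sin(np.pi * t)
        assert snr(v, np.zeros_like(v), t) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_energy_ratio(self, rng):
        t = np.linspace(0, 2, 1200)
        v = 20 * np.sin(np.pi * t / 2)
        noise = rng.normal(0, 1, len(t))
        scale = np.sqrt(np.trapezoid(v**2, t) / (10 * np.trapezoid(noise**2, t)))
        assert snr(v, v + scale * noise, t) == pytest.approx(10.0, abs=0.1)

    def test_monotone_in_noise_amplitude(self, rng):
        t = np.linspace(0, 2, 600)
        v = 20 * np.sin(np.pi * t / 2)
        noise = rng.normal(0, 1, len(t))
        values = [snr(v, v + a * noise, t) for a in (0.1, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(values) < 0)

    def test_zero_signal_undefined(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            snr(np.zeros_like(t), np.ones_like(t), t)


class TestTwoPhaseFit:
    def check_recovery(self, fit, c1, c2):
        for got, want in ((fit.phase1, c1), (fit.phase2, c2)):
            assert abs(got.D - want.D) / want.D < 0.02
            assert abs(got.sigma - want.sigma) / want.sigma < 0.02
            assert abs(got.mu - want.mu) < 0.02
            assert abs(got.t0 - want.t0) < 0.02

    def test_noiseless_60hz_parameter_recovery(self):
        c1 = LognormalComponent(25.0, 0.0, 0.0, 0.3)
        c2 = LognormalComponent(25.0, 0.4, 0.2, 0.3)
        t = np.arange(0, 8, 1 / 60)
        v = lognormal_value(t, c1) - lognormal_value(t, c2)
        fit = fit_two_phase(v, t)
        assert fit.success
        self.check_recovery(fit, c1, c2)
        assert fit.snr_db >= 25

    def test_single_lobe_flags_failure(self):
        c1 = LognormalComponent(25.0, 0.0, 0.0, 0.3)
        t = np.arange(0, 6, 1 / 60)
        fit = fit_two_phase(lognormal_value(t, c1), t)
        assert not fit.success
        assert fit.failure_reason is not None
        assert not fit.qc_pass

    def test_mirrored_input_identical_after_normalization(self):
        from turnsig.quaternions import _normalize_first_lobe_positive

        c1 = LognormalComponent(25.0, 0.1, -0.3, 0.3)
        c2 = LognormalComponent(25.0, 0.6, 0.1, 0.25)
        t = np.arange(0, 8, 1 / 60)
        v = lognormal_value(t, c1) - lognormal_value(t, c2)
        fit_r = fit_two_phase(_normalize_first_lobe_positive(v), t)
        fit_l = fit_two_phase(_normalize_first_lobe_positive(-v), t)
        assert fit_r.params == fit_l.params

    def test_realignment_property(self):
        # matched lobes: integral of the reconstruction ~ D1 - D2 = 0
        c1 = LognormalComponent(25.0, 0.1, -0.3, 0.3)
        c2 = LognormalComponent(25.0, 0.6, 0.1, 0.25)
        t = np.arange(0, 10, 1 / 60)
        v = lognormal_value(t, c1) - lognormal_value(t, c2)
        fit = fit_two_phase(v, t)
        assert abs(fit.phase1.D - fit.phase2.D) < 0.02 * fit.phase1.D

    def test_summary_renders(self):
        c1 = LognormalComponent(25.0, 0.0, 0.0, 0.3)
        c2 = LognormalComponent(25.0, 0.4, 0.2, 0.3)
        t = np.arange(0, 8, 1 / 60)
        v = lognormal_value(t, c1) - lognormal_value(t, c2)
        text = fit_two_phase(v, t).summary()
        assert "SNR" in text and "phase 1" in text

    def test_model_grid_evaluation(self):
        c1 = LognormalComponent(25.0, 0.0, 0.0, 0.3)
        c2 = LognormalComponent(25.0, 0.4, 0.2, 0.3)
        t = np.arange(0, 8, 1 / 60)
        v = lognormal_value(t, c1) - lognormal_value(t, c2)
        fit = fit_two_phase(v, t)
        assert np.allclose(fit.model(fit.time_grid), fit.v_reconstructed)


class TestSingleComponentRoundTrip:
    """Property: forward-simulate then invert recovers the parameters."""

    def test_seeded_random_draws(self):
        from turnsig.lognormal import _extract_component

        rng = np.random.default_rng(2024)
        for _ in range(50):
            D = rng.uniform(5, 60)
            sigma = rng.uniform(0.1, 0.8)
            mu = rng.uniform(-1.5, 0.5)
            t0 = rng.uniform(0, 1)
            c = LognormalComponent(D, t0, mu, sigma)
            t, v = sample_component(c, fs=240)
            got = _extract_component(v, t, 0.01, "threshold")
            assert abs(got.D - D) / D < 0.02
            assert abs(got.sigma - sigma) / sigma < 0.02
            assert abs(got.mu - mu) < 0.02
            assert abs(got.t0 - t0) < 0.02
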