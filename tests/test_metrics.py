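import numpy as np
import pytest

from turnsig import RunConfig, make_trial
from turnsig.io import TrialEvents
from turnsig.metrics import (
    TraditionalMetrics,
    TurnSegment,
    compute_signature,
    compute_traditional,
    count_steps,
    h2t_max,
    misalignment_onset,
    segment_turn,
    turn_velocity_stats,
)
from turnsig.quaternions import OrientationTrack, enforce_hemisphere


def yaw_track(psi_deg, t, label="x"):
    half = np.radians(psi_deg) / 2
    q = np.stack([np.cos(half), 0 * half, 0 * half, np.sin(half)], axis=1)
    return OrientationTrack(label, t, enforce_hemisphere(q))


def events(**over):
    base = dict(
        participant_id="P01",
        trial_id="normal1",
        pace="normal",
        neutral_window=(0.2, 1.2),
        heel_strikes=[],
        turn_start=6.0,
        turn_end=9.5,
    )
    base.update(over)
    return TrialEvents(**base)


class TestMisalignmentOnset:
    def test_identical_tracks_not_found(self):
        t = np.arange(0, 5, 1 / 60)
        tr = yaw_track(np.zeros(len(t)), t)
        assert misalignment_onset(tr, tr, tr) is None

    def test_step_input_onset(self):
        t = np.arange(0, 5, 1 / 60)
        psi = np.where(t >= 3.0, 10.0, 0.0)
        head = yaw_track(psi, t, "head")
        static = yaw_track(np.zeros(len(t)), t)
        onset = misalignment_onset(head, static, static)
        assert onset == pytest.approx(3.0, abs=1.5 / 60)

    def test_simulated_turn_onset_near_truth(self, clean_trial):
        from scipy.integrate import cumulative_trapezoid

        from turnsig.quaternions import apply_alignment, compute_alignment
        from turnsig.simulate import _raised_cosine_ramp

        nw = clean_trial.events.neutral_window
        aligned = [
            apply_alignment(tr, compute_alignment(tr, nw))
            for tr in (clean_trial.head, clean_trial.trunk, clean_trial.pelvis)
        ]
        onset = misalignment_onset(*aligned)
        gt = clean_trial.ground_truth
        cfg = clean_trial.config
        t = clean_trial.t
        # programmed yaw of each segment
        ramp = _raised_cosine_ramp(
            t, cfg.turn_start_s, cfg.turn_profile_duration_s, cfg.turn_angle_deg
        )
        ramp_pelvis = _raised_cosine_ramp(
            t, cfg.turn_start_s + cfg.pelvis_lag_s,
            cfg.turn_profile_duration_s, cfg.turn_angle_deg,
        )
        h2t = cumulative_trapezoid(gt.velocity(t, cfg.turn_start_s), t, initial=0)
        worst = np.max(
            [np.abs(h2t), np.abs(ramp - ramp_pelvis), np.abs(h2t + ramp - ramp_pelvis)],
            axis=0,
        )
        truth = t[np.argmax(worst > 5.0)]
        assert onset == pytest.approx(truth, abs=0.05)


class TestSegmentTurn:
    def test_bracketing_heel_strikes(self):
        ev = events(heel_strikes=[2.0, 3.1, 4.2], turn_start=3.0, turn_end=4.5)
        seg = segment_turn(ev, misalignment_time=3.5, realignment_time=4.0)
        assert seg.start == 3.1
        assert seg.end == 4.2
        assert seg.source == "assisted"

    def test_annotation_fallback(self):
        ev = events()
        seg = segment_turn(ev)
        assert (seg.start, seg.end) == (6.0, 9.5)
        assert seg.source == "annotation"

    def test_no_bracketing_strikes_raises(self):
        ev = events(heel_strikes=[5.0])
        with pytest.raises(ValueError, match="bracketing"):
            segment_turn(ev, misalignment_time=4.0, realignment_time=6.0)

    def test_simulator_segment_covers_turn(self, clean_trial):
        seg = segment_turn(clean_trial.events)
        cfg = clean_trial.config
        assert seg.start == cfg.turn_start_s
        assert seg.end - seg.start >= cfg.turn_profile_duration_s


class TestH2TMax:
    def test_flat_zero(self):
        t = np.arange(0, 10, 1 / 60)
        assert h2t_max(np.zeros(len(t)), t, TurnSegment(2.0, 8.0)) == 0.0

    def test_injected_peak(self):
        t = np.arange(0, 10, 1 / 60)
        ang = 25.0 * np.exp(-0.5 * ((t - 5.0) / 0.5) ** 2)
        assert h2t_max(ang, t, TurnSegment(2.0, 8.0)) == pytest.approx(25.0, abs=0.01)

    def test_direction_invariance(self):
        t = np.arange(0, 10, 1 / 60)
        ang = 25.0 * np.exp(-0.5 * ((t - 5.0) / 0.5) ** 2)
        seg = TurnSegment(2.0, 8.0)
        assert h2t_max(ang, t, seg) == h2t_max(-ang, t, seg)


class TestCountSteps:
    def test_constant_gravity_zero(self):
        t = np.arange(0, 10, 1 / 60)
        az = np.full(len(t), 9.81)
        assert count_steps(az, t, TurnSegment(2.0, 8.0)) == 0

    def test_injected_bursts(self):
        t = np.arange(0, 10, 1 / 60)
        az = np.full(len(t), 9.81)
        for s in (3.0, 3.8, 4.6, 5.4):
            az += 4.0 * np.exp(-0.5 * ((t - s) / 0.05) ** 2)
        assert count_steps(az, t, TurnSegment(2.0, 8.0)) == 4

    def test_simulator_programmed_steps(self, noisy_trial):
        seg = segment_turn(noisy_trial.events)
        strikes = np.asarray(noisy_trial.events.heel_strikes)
        programmed = int(((strikes >= seg.start) & (strikes <= seg.end)).sum())
        got = count_steps(
            noisy_trial.inertial["az"].to_numpy(),
            noisy_trial.inertial["t"].to_numpy(),
            seg,
        )
        assert got == programmed

    def test_empty_segment_raises(self):
        t = np.arange(0, 1, 1 / 60)
        with pytest.raises(ValueError):
            count_steps(np.ones(len(t)), t, TurnSegment(5.0, 6.0))


class TestTurnVelocityStats:
    def test_constant_rate(self):
        t = np.arange(0, 4, 1 / 60)
        mean, mx = turn_velocity_stats(np.full(len(t), 1.5), t, TurnSegment(0.5, 3.5))
        assert mean == pytest.approx(1.5)
        assert mx == pytest.approx(1.5)

    def test_half_sine_closed_form(self):
        t = np.arange(0, 2, 1 / 600)
        w = 4.0 * np.sin(np.pi * t / 2)
        mean, mx = turn_velocity_stats(w, t, TurnSegment(0.0, 2.0))
        assert mx == pytest.approx(4.0, rel=1e-4)
        assert mean == pytest.approx(2 / np.pi * 4.0, rel=1e-2)

    def test_mean_le_max(self, rng):
        t = np.arange(0, 3, 1 / 60)
        w = rng.normal(0, 1, len(t))
        mean, mx = turn_velocity_stats(w, t, TurnSegment(0.5, 2.5))
        assert mean <= mx


class TestComputeSignature:
    def test_noiseless_recovery(self, clean_trial):
        """On oscillation- and noise-free trials the full kinematic chain
        (alignment, relative orientation, angular velocity, axial profile,
        two-phase fit) recovers the programmed signature."""
        sig = compute_signature(
            clean_trial.head, clean_trial.trunk, clean_trial.events,
            RunConfig(), apply_filter=False,
        )
        gt = clean_trial.ground_truth
        fit = sig.fit
        assert fit.success
        for got, D, t0, mu, sigma in (
            (fit.phase1, gt.D1, gt.t01, gt.mu1, gt.sigma1),
            (fit.phase2, gt.D2, gt.t02, gt.mu2, gt.sigma2),
        ):
            assert abs(got.D - D) / D < 0.02
            assert abs(got.sigma - sigma) / sigma < 0.02
            assert abs(got.mu - mu) < 0.02
            assert abs(got.t0 - t0) < 0.02
        assert fit.snr_db >= 25

    def test_h2tmax_matches_programmed_peak(self, clean_trial):
        from scipy.integrate import cumulative_trapezoid

        sig = compute_signature(
            clean_trial.head, clean_trial.trunk, clean_trial.events,
            RunConfig(), apply_filter=False,
        )
        t = clean_trial.t
        gt = clean_trial.ground_truth
        r = cumulative_trapezoid(
            gt.velocity(t, clean_trial.config.turn_start_s), t, initial=0
        )
        assert sig.H2Tmax == pytest.approx(np.abs(r).max(), abs=1.0)

    def test_angle_velocity_consistency(self, clean_trial):
        # H2Tmax ~ extremum of the integrated fitted velocity profile
        sig = compute_signature(
            clean_trial.head, clean_trial.trunk, clean_trial.events,
            RunConfig(), apply_filter=False,
        )
        from scipy.integrate import cumulative_trapezoid

        fit = sig.fit
        integral = cumulative_trapezoid(fit.v_measured, fit.time_grid, initial=0)
        assert sig.H2Tmax == pytest.approx(np.abs(integral).max(), abs=1.0)

    def test_determinism(self, noisy_trial):
        a = compute_signature(
            noisy_trial.head, noisy_trial.trunk, noisy_trial.events, RunConfig()
        )
        b = compute_signature(
            noisy_trial.head, noisy_trial.trunk, noisy_trial.events, RunConfig()
        )
        assert a.as_row() == b.as_row()

    def test_default_pipeline_fits_noisy_trial(self, noisy_trial):
        sig = compute_signature(
            noisy_trial.head, noisy_trial.trunk, noisy_trial.events, RunConfig()
        )
        assert sig.fit.success
        assert np.isfinite(sig.snr_db)


class TestComputeTraditional:
    def test_on_simulated_trial(self, noisy_trial):
        trad = compute_traditional(noisy_trial.inertial, noisy_trial.events)
        assert trad.nb_steps >= 3
        assert trad.turnvel_max >= trad.turnvel_mean > 0
        # trunk ramp peak rate: pi * amp / duration for a raised cosine
        cfg = noisy_trial.config
        peak = np.pi * np.radians(cfg.turn_angle_deg) / (2 * cfg.turn_profile_duration_s)
        assert trad.turnvel_max == pytest.approx(peak, rel=0.1)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TraditionalMetrics(-1, 1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            TraditionalMetrics(3, 2.0, 1.0, 2.0)
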