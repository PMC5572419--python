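"""Synthetic TUG-turn trials with a known cranio-caudal signature.

The generator emulates what the wearable suit records during the turn of a
10-m Timed-Up-and-Go: 60 Hz unit-quaternion streams for head, trunk and
pelvis, plus trunk accelerometer/gyroscope channels, with trial events.

Construction guarantees the ground truth: the trunk yaw follows a smooth
raised-cosine 180-degree ramp, and the head yaw adds the integral of the
two-lognormal relative velocity profile

    v_rel(t) = D1 Lambda(t; t01, mu1, sigma1) - D2 Lambda(t; t02, mu2, sigma2)

so the noiseless axial head-relative-to-trunk angular velocity equals the
analytic curve exactly.  Gait appears as small roll/pitch sinusoids at the
step cadence; orientation noise as small random rotations (unit norm is
preserved); the accelerometer carries gravity, heel-strike impulse bursts
and white noise.  Constant per-segment sensor-mounting offsets exercise the
neutral-pose alignment.  All randomness derives from the seed.

Default parameter values mirror the dispersions reported for healthy older
adults (command amplitudes near 25 degrees, response times 0.2-0.3 s, a
~2.2 s turn at normal pace); they are generator inputs, not asserted truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .io import TrialEvents, write_orientation_track, write_trial_events, write_trunk_inertial
from .lognormal import LognormalComponent, lognormal_value
from .quaternions import OrientationTrack, enforce_hemisphere, quat_multiply

__all__ = ["GroundTruth", "SimConfig", "SyntheticTrial", "make_trial",
           "make_cohort", "write_trial"]

_GRAVITY = 9.81


class GroundTruth(BaseModel):
    """Signature parameters embedded in a synthetic trial (times relative to
    turn start)."""

    D1: float = 25.0
    D2: float = 25.0
    t01: float = 0.1
    t02: float = 0.6
    mu1: float = -0.3
    mu2: float = 0.1
    sigma1: float = 0.3
    sigma2: float = 0.25

    def components(self, origin: float = 0.0) -> tuple[LognormalComponent, LognormalComponent]:
        return (
            LognormalComponent(self.D1, origin + self.t01, self.mu1, self.sigma1),
            LognormalComponent(self.D2, origin + self.t02, self.mu2, self.sigma2),
        )

    def velocity(self, t: np.ndarray, origin: float = 0.0) -> np.ndarray:
        c1, c2 = self.components(origin)
        return lognormal_value(t, c1) - lognormal_value(t, c2)


class GaitConfig(BaseModel):
    cadence_hz: float = Field(1.8, gt=0)
    step_impulse: float = Field(3.0, gt=0)   # m/s^2 burst at heel strike
    roll_amp_deg: float = 2.0
    pitch_amp_deg: float = 1.0


class NoiseConfig(BaseModel):
    orientation_deg: float = Field(0.3, ge=0)  # SD of small random rotations
    accel: float = Field(0.3, ge=0)            # m/s^2 white noise
    gyro: float = Field(0.02, ge=0)            # rad/s white noise


class SimConfig(BaseModel):
    """Study conditions for one synthetic trial."""

    fs: float = Field(60.0, gt=0)
    duration_s: float = 12.0
    turn_angle_deg: float = 180.0
    turn_start_s: float = 6.0
    turn_profile_duration_s: float = 2.2   # raised-cosine trunk yaw ramp
    turn_window_s: float = 3.5             # annotated segment length
    walk_start_s: float = 1.5
    neutral_window: tuple[float, float] = (0.2, 1.2)
    pace: str = "normal"
    fast_duration_scale: float = 0.75      # trunk ramp scaling at fast pace
    pelvis_lag_s: float = 0.15
    mount_offset_deg: float = 8.0          # max per-segment mounting offset
    ground_truth: GroundTruth = Field(default_factory=GroundTruth)
    gait: GaitConfig = Field(default_factory=GaitConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    participant_id: str = "P01"
    trial_id: str = "normal1"

    def model_post_init(self, _ctx) -> None:
        if self.fs <= 2 * self.gait.cadence_hz:
            raise ValueError("sampling rate must exceed twice the cadence")
        gt = self.ground_truth
        lobe2_end = (
            self.turn_start_s + gt.t02 + np.exp(gt.mu2 + 4 * gt.sigma2)
        )
        if lobe2_end > self.duration_s:
            raise ValueError(
                f"phase-2 lobe extends to {lobe2_end:.2f} s, past trial end"
            )


@dataclass
class SyntheticTrial:
    head: OrientationTrack
    trunk: OrientationTrack
    pelvis: OrientationTrack
    inertial: pd.DataFrame
    events: TrialEvents
    ground_truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)  # type: ignore

    @property
    def t(self) -> np.ndarray:
        return self.head.t


def _yaw_quat(psi_rad: np.ndarray) -> np.ndarray:
    half = np.asarray(psi_rad) / 2.0
    z = np.zeros_like(half)
    return np.stack([np.cos(half), z, z, np.sin(half)], axis=-1)


def _euler_quat(roll: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Small roll (x) then pitch (y) oscillation quaternion."""
    hr, hp = roll / 2.0, pitch / 2.0
    qr = np.stack([np.cos(hr), np.sin(hr), np.zeros_like(hr), np.zeros_like(hr)], axis=-1)
    qp = np.stack([np.cos(hp), np.zeros_like(hp), np.sin(hp), np.zeros_like(hp)], axis=-1)
    return quat_multiply(qr, qp)


def _random_rotation_quats(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    """Small random rotations: rotation-vector components ~ N(0, sd)."""
    rv = np.radians(rng.normal(0.0, sd_deg, size=(n, 3)))
    angle = np.linalg.norm(rv, axis=1)
    half = angle / 2.0
    q = np.empty((n, 4))
    q[:, 0] = np.cos(half)
    small = angle < 1e-12
    axis = np.where(small[:, None], np.array([0.0, 0.0, 1.0]), rv / np.where(angle == 0, 1.0, angle)[:, None])
    q[:, 1:] = np.sin(half)[:, None] * axis
    return q


def _raised_cosine_ramp(t: np.ndarray, start: float, duration: float, amp: float) -> np.ndarray:
    """Smooth monotone ramp 0 -> amp with zero endpoint rates."""
    x = np.clip((t - start) / duration, 0.0, 1.0)
    return amp * 0.5 * (1.0 - np.cos(np.pi * x))


def make_trial(cfg: SimConfig | None = None, seed: int = 0) -> SyntheticTrial:
    """Generate one synthetic TUG-turn trial, reproducible from the seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    t = np.arange(0.0, cfg.duration_s, 1.0 / fs)
    n = len(t)

    turn_dur = cfg.turn_profile_duration_s
    if cfg.pace == "fast":
        turn_dur *= cfg.fast_duration_scale

    # trunk yaw ramp and relative head-trunk angle from the signature
    psi_trunk = np.radians(
        _raised_cosine_ramp(t, cfg.turn_start_s, turn_dur, cfg.turn_angle_deg)
    )
    v_rel = cfg.ground_truth.velocity(t, origin=cfg.turn_start_s)  # deg/s
    from scipy.integrate import cumulative_trapezoid

    r_deg = cumulative_trapezoid(v_rel, t, initial=0.0)
    psi_head = psi_trunk + np.radians(r_deg)
    psi_pelvis = np.radians(
        _raised_cosine_ramp(
            t, cfg.turn_start_s + cfg.pelvis_lag_s, turn_dur, cfg.turn_angle_deg
        )
    )

    # gait oscillations, ramped in once walking starts
    cad = cfg.gait.cadence_hz
    walking = 0.5 * (1.0 + np.tanh((t - cfg.walk_start_s) / 0.2))
    roll = np.radians(cfg.gait.roll_amp_deg) * walking * np.sin(2 * np.pi * cad * t)
    pitch = np.radians(cfg.gait.pitch_amp_deg) * walking * np.sin(4 * np.pi * cad * t)

    tracks = {}
    for label, psi, osc_scale in (
        ("head", psi_head, 0.5),
        ("trunk", psi_trunk, 1.0),
        ("pelvis", psi_pelvis, 1.2),
    ):
        q_pose = quat_multiply(
            _yaw_quat(psi), _euler_quat(osc_scale * roll, osc_scale * pitch)
        )
        mount = _random_rotation_quats(
            rng, 1, cfg.mount_offset_deg / 3.0
        )[0]  # ~N(0, max/3) per axis keeps offsets within the stated max
        q_sensor = quat_multiply(q_pose, np.broadcast_to(mount, q_pose.shape))
        if cfg.noise.orientation_deg > 0:
            q_noise = _random_rotation_quats(rng, n, cfg.noise.orientation_deg)
            q_sensor = quat_multiply(q_sensor, q_noise)
        tracks[label] = OrientationTrack(label, t, enforce_hemisphere(q_sensor))

    # heel strikes from walk start to the end of the turn window
    stride = 1.0 / cad
    turn_end = cfg.turn_start_s + cfg.turn_window_s
    strikes = np.arange(cfg.walk_start_s, min(turn_end + 2 * stride, cfg.duration_s - 0.2), stride)

    # trunk inertial channels
    az = np.full(n, _GRAVITY)
    width = 0.05
    for s in strikes:
        az += cfg.gait.step_impulse * np.exp(-0.5 * ((t - s) / width) ** 2)
    gz = np.gradient(psi_trunk, t)
    if cfg.noise.accel > 0:
        az = az + rng.normal(0.0, cfg.noise.accel, n)
    ax = rng.normal(0.0, cfg.noise.accel, n) if cfg.noise.accel > 0 else np.zeros(n)
    ay = rng.normal(0.0, cfg.noise.accel, n) if cfg.noise.accel > 0 else np.zeros(n)
    if cfg.noise.gyro > 0:
        gz = gz + rng.normal(0.0, cfg.noise.gyro, n)
    gx = rng.normal(0.0, cfg.noise.gyro, n) if cfg.noise.gyro > 0 else np.zeros(n)
    gy = rng.normal(0.0, cfg.noise.gyro, n) if cfg.noise.gyro > 0 else np.zeros(n)
    inertial = pd.DataFrame(
        {"t": t, "ax": ax, "ay": ay, "az": az, "gx": gx, "gy": gy, "gz": gz}
    )

    events = TrialEvents(
        participant_id=cfg.participant_id,
        trial_id=cfg.trial_id,
        pace=cfg.pace,
        neutral_window=cfg.neutral_window,
        heel_strikes=[float(s) for s in strikes],
        turn_start=cfg.turn_start_s,
        turn_end=turn_end,
    )
    return SyntheticTrial(
        tracks["head"], tracks["trunk"], tracks["pelvis"],
        inertial, events, cfg.ground_truth, cfg,
    )


def make_cohort(
    cfg: SimConfig | None = None,
    n_participants: int = 16,
    trials_per_condition: int = 2,
    between_subject_sd: float = 6.0,
    within_subject_sd: float = 2.0,
    seed: int = 0,
) -> list[SyntheticTrial]:
    """Simulate a cohort: repeated normal- and fast-pace trials per participant.

    Command amplitudes D1/D2 receive participant-level (between-subject) and
    trial-level (within-subject) Gaussian variation with the given SDs in
    degrees; timing parameters receive proportionally scaled jitter
    (t0: x0.02 s/deg, mu: x0.015 /deg, sigma: x0.008 /deg of the D SDs) so
    the whole signature varies coherently.  Reproducible from the seed.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    base = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    scale = {"t0": 0.02, "mu": 0.015, "sigma": 0.008}
    trials: list[SyntheticTrial] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        gt0 = base.ground_truth
        part = {
            "D1": gt0.D1 + rng.normal(0, between_subject_sd),
            "D2": gt0.D2 + rng.normal(0, between_subject_sd),
            "t01": gt0.t01 + rng.normal(0, scale["t0"] * between_subject_sd),
            "t02": gt0.t02 + rng.normal(0, scale["t0"] * between_subject_sd),
            "mu1": gt0.mu1 + rng.normal(0, scale["mu"] * between_subject_sd),
            "mu2": gt0.mu2 + rng.normal(0, scale["mu"] * between_subject_sd),
            "sigma1": gt0.sigma1 + rng.normal(0, scale["sigma"] * between_subject_sd),
            "sigma2": gt0.sigma2 + rng.normal(0, scale["sigma"] * between_subject_sd),
        }
        part["D1"] = max(part["D1"], 5.0)
        part["D2"] = max(part["D2"], 5.0)
        part["sigma1"] = float(np.clip(part["sigma1"], 0.12, 0.6))
        part["sigma2"] = float(np.clip(part["sigma2"], 0.12, 0.6))
        part["t01"] = max(part["t01"], 0.0)
        part["t02"] = max(part["t02"], part["t01"] + 0.3)
        for pace in ("normal", "fast"):
            for rep in range(trials_per_condition):
                trial_gt = dict(part)
                trial_gt["D1"] += rng.normal(0, within_subject_sd)
                trial_gt["D2"] += rng.normal(0, within_subject_sd)
                trial_gt["t01"] += rng.normal(0, scale["t0"] * within_subject_sd)
                trial_gt["t02"] += rng.normal(0, scale["t0"] * within_subject_sd)
                trial_gt["mu1"] += rng.normal(0, scale["mu"] * within_subject_sd)
                trial_gt["mu2"] += rng.normal(0, scale["mu"] * within_subject_sd)
                trial_gt["sigma1"] += rng.normal(0, scale["sigma"] * within_subject_sd)
                trial_gt["sigma2"] += rng.normal(0, scale["sigma"] * within_subject_sd)
                trial_gt["D1"] = max(trial_gt["D1"], 5.0)
                trial_gt["D2"] = max(trial_gt["D2"], 5.0)
                trial_gt["sigma1"] = float(np.clip(trial_gt["sigma1"], 0.12, 0.6))
                trial_gt["sigma2"] = float(np.clip(trial_gt["sigma2"], 0.12, 0.6))
                trial_gt["t01"] = max(trial_gt["t01"], 0.0)
                trial_gt["t02"] = max(trial_gt["t02"], trial_gt["t01"] + 0.3)
                # keep the phase-2 lobe inside the trial: t02 + e^(mu2+4*sigma2)
                # must end before the recording does (0.5 s margin)
                budget = base.duration_s - base.turn_start_s - trial_gt["t02"] - 0.5
                cap = float(np.log(max(budget, 1.0)))
                if trial_gt["mu2"] + 4 * trial_gt["sigma2"] > cap:
                    trial_gt["sigma2"] = max(
                        (cap - trial_gt["mu2"]) / 4.0, 0.12
                    )
                    trial_gt["mu2"] = min(
                        trial_gt["mu2"], cap - 4 * trial_gt["sigma2"]
                    )
                tcfg = base.model_copy(
                    update={
                        "ground_truth": GroundTruth(**trial_gt),
                        "pace": pace,
                        "participant_id": pid,
                        "trial_id": f"{pace}{rep + 1}",
                    }
                )
                trials.append(
                    make_trial(tcfg, seed=int(rng.integers(0, 2**31 - 1)))
                )
    return trials


def write_trial(trial: SyntheticTrial, directory: str | Path) -> None:
    """Write the full per-trial file set (CSV x4, events + ground-truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_orientation_track(trial.head, directory / "head.csv")
    write_orientation_track(trial.trunk, directory / "trunk.csv")
    write_orientation_track(trial.pelvis, directory / "pelvis.csv")
    write_trunk_inertial(trial.inertial, directory / "trunk_inertial.csv")
    write_trial_events(trial.events, directory / "events.json")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(trial.ground_truth.model_dump(), fh, indent=2)
        fh.write("\n")
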