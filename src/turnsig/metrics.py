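"""Turn segmentation, signature metrics, and traditional turn metrics.

The end-to-end extraction chain for one trial:

    head/trunk quaternions -> neutral-pose alignment -> relative orientation
    -> zero-phase low-pass of the relative angle -> back to quaternions
    -> relative angular velocity -> axial projection (deg/s)
    -> turn segment -> H2Tmax + two-phase sigma-lognormal fit
    -> per-trial metric row (with SNR quality gate)

Traditional comparison metrics come from the trunk inertial channels:
step count from a band-passed vertical acceleration peak detector, and
mean/max axial angular velocity from the trunk gyroscope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .filtering import FilterSpec, filter_track
from .io import RunConfig, TrialEvents
from .lognormal import SigmaLognormalFit, TurnSignatureModel
from .quaternions import (
    OrientationTrack,
    angular_velocity,
    apply_alignment,
    axial_angle,
    axial_component,
    compute_alignment,
    relative_orientation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TurnSegment",
    "SignatureMetrics",
    "TraditionalMetrics",
    "misalignment_onset",
    "segment_turn",
    "h2t_max",
    "count_steps",
    "turn_velocity_stats",
    "compute_signature",
    "compute_traditional",
]


@dataclass(frozen=True)
class TurnSegment:
    start: float
    end: float
    source: str = "annotation"  # or "assisted"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    def mask(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start) & (t <= self.end)


@dataclass
class SignatureMetrics:
    """Per-trial cranio-caudal signature outcome row."""

    participant_id: str
    trial_id: str
    pace: str
    H2Tmax: float
    snr_db: float
    qc_pass: bool
    fit: SigmaLognormalFit

    def as_row(self) -> dict:
        f = self.fit
        p1, p2 = f.phase1, f.phase2
        return {
            "participant_id": self.participant_id,
            "trial_id": self.trial_id,
            "pace": self.pace,
            "H2Tmax": self.H2Tmax,
            "D1": p1.D if p1 else np.nan,
            "D2": p2.D if p2 else np.nan,
            "t01": p1.t0 if p1 else np.nan,
            "t02": p2.t0 if p2 else np.nan,
            "tbar1": p1.tbar if p1 else np.nan,
            "tbar2": p2.tbar if p2 else np.nan,
            "s1": p1.s_resp if p1 else np.nan,
            "s2": p2.s_resp if p2 else np.nan,
            "SNR": self.snr_db,
            "qc_pass": self.qc_pass,
        }


@dataclass
class TraditionalMetrics:
    nb_steps: int
    turnvel_mean: float
    turnvel_max: float
    turn_duration: float

    def __post_init__(self) -> None:
        if self.nb_steps < 0:
            raise ValueError("nb_steps must be >= 0")
        if not (self.turnvel_max >= self.turnvel_mean >= 0):
            raise ValueError("turnvel_max >= turnvel_mean >= 0 required")

    def as_row(self) -> dict:
        return {
            "NbSteps": self.nb_steps,
            "turnvel_mean": self.turnvel_mean,
            "turnvel_max": self.turnvel_max,
        }


# --------------------------------------------------------------------------
# segmentation


def misalignment_onset(
    head: OrientationTrack,
    trunk: OrientationTrack,
    pelvis: OrientationTrack,
    threshold_deg: float = 5.0,
    sustain_s: float = 0.2,
) -> float | None:
    """Assisted segmentation helper: earliest time the head-trunk-pelvis
    axis misaligns.

    Returns the first time at which the maximum pairwise axial angle among
    the three segments exceeds ``threshold_deg`` sustained for at least
    ``sustain_s``; ``None`` if it never does.  Final turn boundaries come
    from heel-strike annotations.
    """
    t = head.t
    pair_angles = [
        np.abs(axial_angle(relative_orientation(a, b)))
        for a, b in ((head, trunk), (trunk, pelvis), (head, pelvis))
    ]
    worst = np.max(pair_angles, axis=0)
    above = worst > threshold_deg
    n_sustain = max(1, int(round(sustain_s * head.sampling_rate)))
    # first index i such that above[i : i + n_sustain] is all True
    kernel = np.ones(n_sustain, dtype=int)
    runs = np.convolve(above.astype(int), kernel, mode="valid")
    hits = np.nonzero(runs == n_sustain)[0]
    if len(hits) == 0:
        return None
    return float(t[hits[0]])


def segment_turn(
    events: TrialEvents,
    misalignment_time: float | None = None,
    realignment_time: float | None = None,
) -> TurnSegment:
    """Turn boundaries from annotations.

    With heel strikes and misalignment/realignment times: start is the
    latest heel strike at/before the misalignment onset, end the earliest
    heel strike at/after realignment.  Otherwise the annotated turn_start
    and turn_end are used verbatim.
    """
    strikes = np.asarray(events.heel_strikes, dtype=float)
    if misalignment_time is not None and realignment_time is not None and len(strikes):
        before = strikes[strikes <= misalignment_time]
        after = strikes[strikes >= realignment_time]
        if len(before) == 0 or len(after) == 0:
            raise ValueError("no heel strikes bracketing the turn")
        return TurnSegment(float(before.max()), float(after.min()), "assisted")
    return TurnSegment(events.turn_start, events.turn_end, "annotation")


# --------------------------------------------------------------------------
# metric primitives


def h2t_max(
    relative_angle_deg: np.ndarray, t: np.ndarray, seg: TurnSegment
) -> float:
    """Maximum magnitude of the axial relative angle within the segment."""
    m = seg.mask(np.asarray(t, dtype=float))
    if not m.any():
        raise ValueError("segment contains no samples")
    return float(np.max(np.abs(np.asarray(relative_angle_deg)[m])))


def count_steps(
    trunk_accel: np.ndarray,
    t: np.ndarray,
    seg: TurnSegment,
    threshold: float = 1.2,
    band_hz: tuple[float, float] = (0.5, 3.0),
    refractory_s: float = 0.25,
) -> int:
    """Heel-strike count from the trunk vertical acceleration in the segment.

    The channel is band-passed (0.5-3 Hz, 2nd-order zero-phase Butterworth);
    peaks exceeding ``threshold`` (m/s^2, relative to the band-passed zero
    baseline) separated by at least ``refractory_s`` are counted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t, dtype=float)
    a = np.asarray(trunk_accel, dtype=float)
    m = seg.mask(t)
    if not m.any():
        raise ValueError("segment contains no acceleration samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    sos = sps.butter(2, band_hz, btype="band", fs=fs, output="sos")
    # filter the full series to avoid segment-edge transients, then crop
    a_f = sps.sosfiltfilt(sos, a)
    seg_sig = a_f[m]
    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = sps.find_peaks(seg_sig, height=threshold, distance=distance)
    return int(len(peaks))


def turn_velocity_stats(
    trunk_gyro_axial: np.ndarray, t: np.ndarray, seg: TurnSegment
) -> tuple[float, float]:
    """(mean, max) of |axial trunk angular rate| within the segment, rad/s."""
    t = np.asarray(t, dtype=float)
    m = seg.mask(t)
    if not m.any():
        raise ValueError("segment contains no gyro samples")
    w = np.abs(np.asarray(trunk_gyro_axial, dtype=float)[m])
    return float(w.mean()), float(w.max())


# --------------------------------------------------------------------------
# end-to-end


def _relative_velocity_profile(
    head: OrientationTrack,
    trunk: OrientationTrack,
    events: TrialEvents,
    cfg: RunConfig,
    apply_filter: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, axial velocity deg/s, axial relative angle deg), full trial."""
    align_h = compute_alignment(head, events.neutral_window)
    align_t = compute_alignment(trunk, events.neutral_window)
    head_a = apply_alignment(head, align_h)
    trunk_a = apply_alignment(trunk, align_t)
    rel = relative_orientation(head_a, trunk_a)
    if apply_filter:
        spec = FilterSpec(
            cfg.filter_order, cfg.cutoff_hz, head.sampling_rate, zero_phase=True
        )
        rel = filter_track(rel, spec)
    avt = angular_velocity(rel)
    v_axial = np.degrees(axial_component(avt))  # deg/s, first lobe positive
    angle = axial_angle(rel)
    # match the direction normalization applied to the velocity
    if len(angle) and np.max(angle, initial=0.0) < -np.min(angle, initial=0.0):
        angle = -angle
    return rel.t, v_axial, angle


def compute_signature(
    head: OrientationTrack,
    trunk: OrientationTrack,
    events: TrialEvents,
    cfg: RunConfig | None = None,
    apply_filter: bool = True,
) -> SignatureMetrics:
    """Full signature extraction for one trial."""
    cfg = cfg or RunConfig()
    t, v_axial, angle = _relative_velocity_profile(
        head, trunk, events, cfg, apply_filter
    )
    seg = segment_turn(events)
    m = seg.mask(t)
    if m.sum() < 10:
        raise ValueError("turn segment holds fewer than 10 samples")
    h2t = h2t_max(angle, t, seg)
    model = TurnSignatureModel(
        v_axial[m],
        t[m] - seg.start,  # t0 reported relative to turn start
        snr_gate_db=cfg.snr_gate_db,
        p1p5_fraction=cfg.p1p5_fraction,
    )
    fit = model.fit()
    if not fit.success:
        logger.warning(
            "trial %s/%s: signature fit failed (%s)",
            events.participant_id,
            events.trial_id,
            fit.failure_reason,
        )
    return SignatureMetrics(
        participant_id=events.participant_id,
        trial_id=events.trial_id,
        pace=events.pace,
        H2Tmax=h2t,
        snr_db=fit.snr_db,
        qc_pass=fit.qc_pass,
        fit=fit,
    )


def compute_traditional(
    inertial,
    events: TrialEvents,
    cfg: RunConfig | None = None,
) -> TraditionalMetrics:
    """Traditional turn metrics from the trunk inertial CSV channels."""
    cfg = cfg or RunConfig()
    seg = segment_turn(events)
    t = inertial["t"].to_numpy(dtype=float)
    nb = count_steps(
        inertial["az"].to_numpy(dtype=float), t, seg, cfg.step_accel_threshold
    )
    mean_w, max_w = turn_velocity_stats(
        inertial["gz"].to_numpy(dtype=float), t, seg
    )
    return TraditionalMetrics(
        nb_steps=nb,
        turnvel_mean=mean_w,
        turnvel_max=max_w,
        turn_duration=seg.end - seg.start,
    )
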