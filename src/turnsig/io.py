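"""File formats and run configuration.

Formats
-------
Orientation CSV   header ``t,qw,qx,qy,qz`` — one body segment per file,
                  scalar-first unit quaternions at the sensor rate (60 Hz).
Trunk inertial CSV  header ``t,ax,ay,az,gx,gy,gz`` — accelerometer (m/s^2)
                  and gyroscope (rad/s) channels in the sensor frame.
Events JSON       keys ``participant_id, trial_id, pace, neutral_window,
                  heel_strikes, turn_start, turn_end``.
Metrics TSV       one row per trial; signature metrics (H2Tmax, D1, D2,
                  t01, t02, tbar1, tbar2, s1, s2) plus the traditional
                  metrics (NbSteps, turnvel_mean, turnvel_max), SNR and the
                  QC flag.

All times are seconds, float, relative to the recording start.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .quaternions import OrientationTrack, enforce_hemisphere, quat_multiply

__all__ = [
    "RunConfig",
    "TrialEvents",
    "FormatError",
    "METRIC_COLUMNS",
    "read_orientation_track",
    "write_orientation_track",
    "read_trunk_inertial",
    "write_trunk_inertial",
    "read_trial_events",
    "write_trial_events",
    "write_metrics_table",
    "read_metrics_table",
]

_QNORM_TOL = 1e-3
_MAX_GAP_SAMPLES = 3


class FormatError(ValueError):
    """A file does not match its declared format or schema."""


class RunConfig(BaseModel):
    """Extraction-pipeline configuration with the study defaults."""

    cutoff_hz: float = Field(1.5, gt=0)
    filter_order: int = Field(4, ge=1)
    residual_threshold_deg: float = Field(2.0, gt=0)
    snr_gate_db: float = Field(10.0, gt=0)
    step_accel_threshold: float = Field(1.2, gt=0)  # m/s^2 above segment median
    p1p5_fraction: float = Field(0.01, gt=0, lt=0.5)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


class TrialEvents(BaseModel):
    """Per-trial annotations: neutral pose, gait events, turn boundaries."""

    participant_id: str
    trial_id: str
    pace: str
    neutral_window: tuple[float, float]
    heel_strikes: list[float] = Field(default_factory=list)
    turn_start: float
    turn_end: float

    @field_validator("pace")
    @classmethod
    def _pace_known(cls, v: str) -> str:
        if v not in ("normal", "fast"):
            raise ValueError(f"unknown pace label {v!r}")
        return v

    @model_validator(mode="after")
    def _ordering(self) -> "TrialEvents":
        if self.turn_end <= self.turn_start:
            raise ValueError("turn_end must exceed turn_start")
        if self.neutral_window[1] > self.turn_start:
            raise ValueError("neutral window must precede turn_start")
        if any(
            b < a
            for a, b in zip(self.heel_strikes[:-1], self.heel_strikes[1:])
        ):
            raise ValueError("heel_strikes must be sorted")
        return self


def read_orientation_track(
    path: str | Path,
    segment_label: str = "unknown",
    sampling_rate: float = 60.0,
) -> OrientationTrack:
    """Load an orientation CSV into a normalized, hemisphere-continuous track.

    Validates quaternion norms (within 1e-3 of 1 before normalization) and
    time monotonicity; gaps shorter than 3 nominal samples are filled by
    spherical linear interpolation, larger gaps raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["t", "qw", "qx", "qy", "qz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    if len(t) == 0:
        raise FormatError(f"{path}: empty file")
    dt_rows = np.diff(t)
    if np.any(dt_rows <= 0):
        row = int(np.argmax(dt_rows <= 0)) + 1
        raise FormatError(f"{path}: non-monotone time at row {row}")
    norms = np.linalg.norm(q, axis=1)
    bad = np.abs(norms - 1.0) > _QNORM_TOL
    if np.any(bad):
        row = int(np.argmax(bad))
        raise FormatError(
            f"{path}: quaternion norm {norms[row]:.4f} at row {row} "
            f"deviates from 1 by more than {_QNORM_TOL}"
        )
    q = q / norms[:, None]
    q = enforce_hemisphere(q)

    dt = 1.0 / sampling_rate
    n_expected = int(round((t[-1] - t[0]) / dt)) + 1
    uniform = np.allclose(np.diff(t), dt, atol=dt * 0.05)
    if uniform and n_expected == len(t):
        return OrientationTrack(segment_label, t, q)

    # resample onto the uniform grid by slerp; reject long gaps
    gaps = np.diff(t) / dt
    if np.any(gaps > _MAX_GAP_SAMPLES + 0.5):
        row = int(np.argmax(gaps > _MAX_GAP_SAMPLES + 0.5))
        raise FormatError(
            f"{path}: gap of {gaps[row]:.1f} samples after row {row} "
            f"exceeds the {_MAX_GAP_SAMPLES}-sample limit"
        )
    from scipy.spatial.transform import Rotation, Slerp

    t_new = t[0] + dt * np.arange(n_expected)
    t_new = t_new[t_new <= t[-1] + 1e-9]
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to scalar-last
    interp = Slerp(t, rot)
    q_new = interp(np.clip(t_new, t[0], t[-1])).as_quat()[:, [3, 0, 1, 2]]
    return OrientationTrack(segment_label, t_new, enforce_hemisphere(q_new))


def write_orientation_track(track: OrientationTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": track.t,
            "qw": track.q[:, 0],
            "qx": track.q[:, 1],
            "qy": track.q[:, 2],
            "qz": track.q[:, 3],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


_INERTIAL_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def read_trunk_inertial(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _INERTIAL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        raise FormatError(f"{path}: non-monotone time")
    return df[_INERTIAL_COLS].astype(float)


def write_trunk_inertial(df: pd.DataFrame, path: str | Path) -> None:
    df[_INERTIAL_COLS].to_csv(path, index=False, float_format="%.9g")


def read_trial_events(path: str | Path) -> TrialEvents:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return TrialEvents.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError -> schema error
        raise FormatError(f"{path}: {exc}") from exc


def write_trial_events(events: TrialEvents, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(events.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


METRIC_COLUMNS = [
    "participant_id",
    "trial_id",
    "pace",
    "H2Tmax",
    "D1",
    "D2",
    "t01",
    "t02",
    "tbar1",
    "tbar2",
    "s1",
    "s2",
    "NbSteps",
    "turnvel_mean",
    "turnvel_max",
    "SNR",
    "qc_pass",
]


def write_metrics_table(rows: list[dict], path: str | Path) -> None:
    """Write per-trial metric rows as a TSV with the canonical column set.

    Rows failing QC are still written; filtering happens downstream in the
    reliability analysis.
    """
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metric column(s) {missing}")
    return df
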