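"""Quaternion algebra and relative head-to-trunk kinematics.

Orientation streams from body-worn AHRS modules arrive as unit quaternions
(scalar-first, one per sample).  This module provides the small amount of
quaternion algebra the pipeline needs, the neutral-pose sensor-to-body
alignment, the relative orientation of one segment with respect to another,
the axis-angle decomposition, and the angular velocity of a rotating frame
reconstructed from the axis-angle time series

    omega(t) = theta_dot * u + u_dot * sin(theta) + (u x u_dot) * (1 - cos(theta))

with derivatives taken by central finite differences (one-sided at the ends).

All quaternions are scalar-first arrays ``(w, x, y, z)``; tracks are
hemisphere-continuous (consecutive dot products >= 0) so that angles and
finite differences are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrientationTrack",
    "AngularVelocityTrack",
    "quat_multiply",
    "quat_conjugate",
    "quat_normalize",
    "enforce_hemisphere",
    "quat_mean",
    "compute_alignment",
    "apply_alignment",
    "relative_orientation",
    "to_axis_angle",
    "axis_angle_to_quat",
    "angular_velocity",
    "axial_component",
    "axial_angle",
]

_EPS_THETA = 1e-8


@dataclass
class OrientationTrack:
    """Timestamped unit-quaternion sequence for one body segment.

    Attributes
    ----------
    segment_label : str
        One of ``head``, ``trunk``, ``pelvis`` (free-form accepted).
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniform.
    q : ndarray, shape (n, 4)
        Scalar-first unit quaternions, hemisphere-continuous.
    """

    segment_label: str
    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("q must have shape (n, 4)")
        if self.t.shape[0] != self.q.shape[0]:
            raise ValueError("t and q lengths differ")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class AngularVelocityTrack:
    """3-component angular velocity (rad/s) plus its axial scalar projection."""

    t: np.ndarray
    omega: np.ndarray
    axial: np.ndarray = field(default=None)  # type: ignore[assignment]
    axis_convention: str = "body-z"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.axial is not None:
            self.axial = np.asarray(self.axial, dtype=float)
            if len(self.axial) != len(self.t):
                raise ValueError("axial and t lengths differ")


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite quaternion input")


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a (x) b. Accepts single quaternions or (n, 4) arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, b)
    aw, ax, ay, az = np.moveaxis(np.atleast_2d(a), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.atleast_2d(b), -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    if a.ndim == 1 and b.ndim == 1:
        return out[0]
    return out


def quat_conjugate(a: np.ndarray) -> np.ndarray:
    """Conjugate: negate the vector part (inverse for unit quaternions)."""
    a = np.asarray(a, dtype=float)
    _check_finite(a)
    return a * np.array([1.0, -1.0, -1.0, -1.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm quaternion")
    return q / norm


def enforce_hemisphere(q: np.ndarray) -> np.ndarray:
    """Flip signs so consecutive quaternion dot products are non-negative.

    q and -q encode the same rotation; sensor streams may flip sign
    arbitrarily, which would break finite differencing of the angle.
    """
    q = np.array(q, dtype=float, copy=True)
    if q.ndim == 1:
        return q
    dots = np.sum(q[1:] * q[:-1], axis=1)
    # cumulative sign: a single flip inverts everything downstream
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def quat_mean(q: np.ndarray) -> np.ndarray:
    """Normalized arithmetic mean of sign-aligned quaternions.

    For tightly clustered rotations (a neutral-pose window) this agrees with
    the geodesic mean to second order in the dispersion.
    """
    q = enforce_hemisphere(np.atleast_2d(np.asarray(q, dtype=float)))
    # align all to the first sample's hemisphere (pairwise continuity already
    # ensures a consistent branch)
    m = q.mean(axis=0)
    return quat_normalize(m)


def compute_alignment(track: OrientationTrack, neutral_window: tuple) -> np.ndarray:
    """Alignment quaternion from a neutral-pose window.

    Returns the conjugate of the window's mean quaternion.  Right-multiplying
    the raw sensor stream by it (``apply_alignment``) yields identity body
    orientation at the neutral pose; any constant sensor-mounting offset
    cancels exactly.

    Raises
    ------
    ValueError
        If the window lies outside the track or holds < 0.5 s of samples.
    """
    t0, t1 = float(neutral_window[0]), float(neutral_window[1])
    if t0 < track.t[0] - 1e-9 or t1 > track.t[-1] + 1e-9:
        raise ValueError(
            f"neutral window [{t0}, {t1}] outside track span "
            f"[{track.t[0]}, {track.t[-1]}]"
        )
    mask = (track.t >= t0) & (track.t <= t1)
    if mask.sum() < max(2, int(0.5 * track.sampling_rate)):
        raise ValueError("neutral window holds less than 0.5 s of samples")
    window = track.q[mask]
    mean = quat_mean(window)
    # dispersion check: geodesic distance of each sample to the mean
    dots = np.clip(np.abs(window @ mean), -1.0, 1.0)
    spread_deg = np.degrees(2 * np.arccos(dots)).max()
    if spread_deg > 5.0:
        import logging

        logging.getLogger(__name__).warning(
            "neutral-pose window dispersion %.1f deg exceeds 5 deg for %s",
            spread_deg,
            track.segment_label,
        )
    return quat_conjugate(mean)


def apply_alignment(track: OrientationTrack, alignment: np.ndarray) -> OrientationTrack:
    """Express the track as rotation-from-neutral: q_aligned = q_sensor (x) alignment."""
    q = quat_multiply(track.q, np.broadcast_to(alignment, track.q.shape))
    return OrientationTrack(track.segment_label, track.t, enforce_hemisphere(q))


def relative_orientation(
    head: OrientationTrack, trunk: OrientationTrack
) -> OrientationTrack:
    """Orientation of the head expressed in the trunk frame.

    q_rel(t) = q_trunk*(t) (x) q_head(t), hemisphere-continuous.
    """
    if len(head) != len(trunk) or not np.allclose(head.t, trunk.t, atol=1e-9):
        raise ValueError("head and trunk tracks have mismatched time bases")
    q_rel = quat_multiply(quat_conjugate(trunk.q), head.q)
    return OrientationTrack("head_rel_trunk", head.t, enforce_hemisphere(q_rel))


def to_axis_angle(track: OrientationTrack) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a hemisphere-continuous track into (theta, u) per sample.

    theta = 2 arccos(clamped w) in radians; u the normalized vector part.
    The decomposition is kept *continuous*: when the rotation passes near
    identity and the raw axis flips by ~180 degrees, the branch
    (theta, u) -> (-theta, -u) — the same rotation — is chosen instead, so
    theta and u stay smooth and the derivatives in the angular-velocity
    formula remain finite.  Near-identity samples (|theta| < 1e-8) carry the
    previous axis forward (axial z at the first sample).
    """
    q = track.q
    w = np.clip(q[:, 0], -1.0, 1.0)
    theta = 2.0 * np.arccos(w)
    vec = q[:, 1:]
    norms = np.linalg.norm(vec, axis=1)
    u = np.zeros_like(vec)
    valid = theta >= _EPS_THETA
    u[valid] = vec[valid] / norms[valid, None]
    last = None
    for i in range(len(theta)):
        if valid[i]:
            if last is not None and u[i] @ last < 0:  # continuity branch
                u[i] = -u[i]
                theta[i] = -theta[i]
            last = u[i]
        else:
            u[i] = last if last is not None else np.array([0.0, 0.0, 1.0])
    return theta, u


def axis_angle_to_quat(theta: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Rebuild scalar-first quaternions from (theta [rad], unit axis)."""
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("axis vectors must be unit norm")
    half = theta / 2.0
    q = np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * u], axis=-1
    )
    return enforce_hemisphere(q)


def _central_diff(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    # np.gradient: central interior, one-sided at the ends
    return np.gradient(x, t, axis=0)


def angular_velocity(track: OrientationTrack) -> AngularVelocityTrack:
    """Angular velocity (rad/s) of a rotating frame from its axis-angle series.

    omega = theta_dot u + u_dot sin(theta) + (u x u_dot)(1 - cos(theta)).
    """
    if len(track) < 3:
        raise ValueError("track shorter than 3 samples")
    theta, u = to_axis_angle(track)
    theta_dot = _central_diff(theta, track.t)
    u_dot = _central_diff(u, track.t)
    omega = (
        theta_dot[:, None] * u
        + u_dot * np.sin(theta)[:, None]
        + np.cross(u, u_dot) * (1.0 - np.cos(theta))[:, None]
    )
    return AngularVelocityTrack(track.t, omega)


def axial_component(
    avt: AngularVelocityTrack,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    normalize_direction: bool = True,
) -> np.ndarray:
    """Project omega onto a unit axis; optionally flip sign so the first lobe
    (head leading the trunk) is positive, making left and right turns
    comparable.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero axial axis")
    if abs(n - 1.0) > 1e-6:
        raise ValueError("axial axis must be unit norm")
    s = avt.omega @ axis
    if normalize_direction:
        s = _normalize_first_lobe_positive(s)
    return s


def _normalize_first_lobe_positive(s: np.ndarray) -> np.ndarray:
    """Flip sign so the earlier of the two dominant opposite-sign extrema is
    positive (turn-direction normalization)."""
    if len(s) == 0 or np.allclose(s, 0):
        return s
    imax = int(np.argmax(s))
    imin = int(np.argmin(s))
    if s[imax] <= 0:
        return -s
    if s[imin] >= 0:
        return s
    return s if imax < imin else -s


def axial_angle(track: OrientationTrack, axis: np.ndarray = (0.0, 0.0, 1.0)) -> np.ndarray:
    """Axial relative angle in degrees: rotation vector projected on the axis."""
    theta, u = to_axis_angle(track)
    axis = np.asarray(axis, dtype=float)
    return np.degrees(theta * (u @ axis))
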