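"""Two-phase sigma-lognormal decomposition of the turn velocity profile.

The kinematic theory of rapid movements models the impulse response of a
neuromuscular system (NMS) as a shifted lognormal in time.  During a turn
the head leads and the trunk catches up, so the axial head-relative-to-trunk
angular-velocity profile is the difference of two lognormal lobes

    v(t) = D1 Lambda(t; t01, mu1, sigma1) - D2 Lambda(t; t02, mu2, sigma2)

where, for each phase, ``D`` is the amplitude of the motor command (degrees,
the area under the velocity lobe), ``t0`` the command occurrence time (s),
``mu`` the log time delay and ``sigma`` the log response time of the NMS.

Parameters are estimated from characteristic points of each lobe — onset
(P1), first inflection (P2), peak (P3), second inflection (P4), offset (P5)
— by closed-form inversion.  Derived quantities:

    tbar  = t0 + exp(mu + sigma^2/2)                 (system time delay)
    s     = (tbar - t0) sqrt(exp(sigma^2) - 1)       (system response time)
    vmax  = D exp(-mu + sigma^2/2) / (sigma sqrt(2 pi))   (peak velocity)

Reconstruction quality is an energy signal-to-noise ratio in dB; a trial is
quality-gated at a configurable threshold (default 10 dB).

The module exposes a statsmodels-style surface: ``TurnSignatureModel``
wraps a velocity profile, ``fit()`` returns a ``SigmaLognormalFit`` results
object with the eight parameters, derived timings, SNR and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import brentq

__all__ = [
    "LognormalComponent",
    "CharacteristicPoints",
    "SigmaLognormalFit",
    "TurnSignatureModel",
    "ExtractionError",
    "lognormal_value",
    "find_characteristic_points",
    "estimate_sigma",
    "estimate_mu_t0_D",
    "derived_timing",
    "snr",
    "fit_two_phase",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_SNR_CAP_DB = 100.0


class ExtractionError(RuntimeError):
    """Characteristic-point extraction or inversion failed for a lobe."""


# --------------------------------------------------------------------------
# components


@dataclass(frozen=True)
class LognormalComponent:
    """One NMS lognormal impulse response: v_i(t) = D Lambda(t; t0, mu, sigma)."""

    D: float
    t0: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def tbar(self) -> float:
        """First moment of the impulse response (system time delay), s."""
        return self.t0 + np.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def s_resp(self) -> float:
        """Response time (spread of the impulse response), s."""
        return (self.tbar - self.t0) * np.sqrt(np.exp(self.sigma**2) - 1.0)

    @property
    def vmax(self) -> float:
        """Peak of the velocity lobe, same units as D per second."""
        return (
            self.D
            * np.exp(-self.mu + 0.5 * self.sigma**2)
            / (self.sigma * _SQRT_2PI)
        )

    @property
    def t_peak(self) -> float:
        """Location of the velocity peak: t0 + exp(mu - sigma^2)."""
        return self.t0 + np.exp(self.mu - self.sigma**2)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return lognormal_value(t, self)

    def shifted(self, dt: float) -> "LognormalComponent":
        return LognormalComponent(self.D, self.t0 + dt, self.mu, self.sigma)


def lognormal_value(t, c: LognormalComponent) -> np.ndarray:
    """D-scaled shifted lognormal density; zero for t <= t0."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    m = t > c.t0
    dt = t[m] - c.t0
    x = np.log(dt)
    out[m] = (
        c.D
        * np.exp(-((x - c.mu) ** 2) / (2.0 * c.sigma**2))
        / (c.sigma * dt * _SQRT_2PI)
    )
    return float(out[0]) if scalar else out


def derived_timing(c: LognormalComponent) -> tuple[float, float]:
    """(tbar, s): system time delay and response time in seconds."""
    return c.tbar, c.s_resp


# --------------------------------------------------------------------------
# characteristic points


@dataclass(frozen=True)
class CharacteristicPoints:
    """P1..P5 of a single velocity lobe: onset, inflections, peak, offset."""

    tP1: float
    tP2: float
    tP3: float
    tP4: float
    tP5: float
    vP3: float

    def __post_init__(self) -> None:
        times = (self.tP1, self.tP2, self.tP3, self.tP4, self.tP5)
        if not all(np.isfinite(times)) or not np.isfinite(self.vP3):
            raise ExtractionError("non-finite characteristic point")
        if not (self.tP1 < self.tP2 < self.tP3 < self.tP4 < self.tP5):
            raise ExtractionError(f"characteristic points out of order: {times}")
        if self.vP3 <= 0:
            raise ExtractionError("non-positive peak velocity")


def _spline_sign_change_roots(d2, grid: np.ndarray) -> np.ndarray:
    vals = d2(grid)
    sgn = np.sign(vals)
    roots = []
    for i in np.nonzero(np.diff(sgn) != 0)[0]:
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(a)
        elif fb == 0.0:
            continue  # picked up at the next interval's left edge
        elif fa * fb < 0:
            roots.append(brentq(d2, a, b))
    return np.asarray(roots)


def _auto_smooth(v: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Savitzky-Golay pre-smoothing for point detection on noisy lobes.

    A cubic SG filter is applied only when the high-frequency residual
    exceeds 0.1% of the peak, so that clean (noiseless) signals are analysed
    exactly as sampled; the window adapts to the dominant lobe width so
    narrow lobes keep their shape.  Returns the (possibly smoothed) signal
    and an estimate of the post-smoothing noise RMS.
    """
    from scipy.signal import savgol_filter

    n = len(v)
    if n < 9:
        return v, 0.0
    fs = 1.0 / float(np.median(np.diff(t)))
    # noise level from the residual of a short local fit (distortion-free
    # for smooth signals)
    noise = np.sqrt(np.mean((v - savgol_filter(v, 7, polyorder=3)) ** 2))
    peak = np.max(np.abs(v))
    if peak <= 0 or noise / peak <= 1e-3:
        return v, 0.0
    # window adapted to the dominant lobe so narrow lobes keep their shape
    i3 = int(np.argmax(np.abs(v)))
    half = 0.5 * peak
    iL = i3
    while iL > 0 and abs(v[iL]) >= half:
        iL -= 1
    iR = i3
    while iR < n - 1 and abs(v[iR]) >= half:
        iR += 1
    fwhm = max(iR - iL, 5)
    win = int(min(round(0.25 * fs), round(0.6 * fwhm))) | 1
    if 5 <= win < n:
        # cubic SG noise gain is roughly sqrt(5 / window)
        return savgol_filter(v, win, polyorder=3), noise * np.sqrt(5.0 / win)
    return v, noise


def _outward_crossing(v, t, sp, i3, thr, direction):
    """Nearest sub-sample crossing of ``thr`` walking outward from the peak,
    so baseline wiggle outside the lobe cannot trigger it early.  Returns
    the boundary time when the signal never drops below the threshold."""
    n = len(v)
    cross = lambda x: float(sp(x)) - thr
    i = i3
    if direction < 0:
        while i > 0 and v[i] >= thr:
            i -= 1
        if v[i] >= thr:
            return float(t[0]), False
        a, b = t[i], t[i + 1]
        if cross(a) * cross(b) < 0:
            return float(brentq(cross, a, b)), True
        return float(a + (b - a) * (thr - v[i]) / (v[i + 1] - v[i])), True
    while i < n - 1 and v[i] >= thr:
        i += 1
    if v[i] >= thr:
        return float(t[-1]), False
    a, b = t[i - 1], t[i]
    if cross(a) * cross(b) < 0:
        return float(brentq(cross, a, b)), True
    return float(a + (b - a) * (v[i - 1] - thr) / (v[i - 1] - v[i])), True


def _locate_points(
    v: np.ndarray, t: np.ndarray, p1p5_fraction: float, smooth: bool = True
) -> dict:
    """Locate the characteristic points of a single positive lobe.

    Returns a dict with tP1..tP5 and vP3; a masked inflection (lobe
    truncated by the other phase) yields ``None`` for tP2/tP4.  Raises only
    for degenerate input (no interior positive maximum, too short).
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(v) < 10:
        raise ExtractionError("lobe shorter than 10 samples")
    noise_rms = 0.0
    if smooth:
        v, noise_rms = _auto_smooth(v, t)
    i3 = int(np.argmax(v))
    if i3 == 0 or i3 == len(v) - 1 or v[i3] <= 0:
        raise ExtractionError("no interior positive maximum (monotone input?)")

    k = 5 if len(v) > 6 else 3
    sp = make_interp_spline(t, v, k=k)
    d1 = sp.derivative(1)
    d2 = sp.derivative(2)

    lo, hi = t[i3 - 1], t[i3 + 1]
    if d1(lo) * d1(hi) < 0:
        tP3 = brentq(d1, lo, hi)
        vP3 = float(sp(tP3))
    else:  # parabolic fallback on the discrete triple
        y0, y1, y2 = v[i3 - 1 : i3 + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        tP3 = t[i3] + shift * (t[i3] - t[i3 - 1])
        vP3 = float(y1 - 0.25 * (y0 - y2) * shift)

    # secondary-maxima ambiguity check
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(v, height=0.5 * vP3)
    if len(peaks) > 1:
        warnings.warn(
            "multiple local maxima above 50% of peak; using the global maximum",
            stacklevel=2,
        )

    grid = np.linspace(t[0], t[-1], max(8 * len(t), 200))
    infl = _spline_sign_change_roots(d2, grid)
    left = infl[infl < tP3]
    right = infl[infl > tP3]
    tP2 = float(left.max()) if len(left) else None
    tP4 = float(right.min()) if len(right) else None

    # the onset/offset fraction is raised above the estimated noise floor so
    # the outward walk cannot stop in noise; the ratio->sigma inversion is
    # parametric in the fraction, so estimates stay consistent
    alpha = float(np.clip(3.0 * noise_rms / vP3, p1p5_fraction, 0.25)) \
        if vP3 > 0 else p1p5_fraction
    thr = alpha * vP3
    tP1, ok1 = _outward_crossing(v, t, sp, i3, thr, -1)
    tP5, ok5 = _outward_crossing(v, t, sp, i3, thr, +1)
    t50_left, okl = _outward_crossing(v, t, sp, i3, 0.5 * vP3, -1)
    t50_right, okr = _outward_crossing(v, t, sp, i3, 0.5 * vP3, +1)

    return {
        "tP1": tP1, "tP2": tP2, "tP3": float(tP3), "tP4": tP4, "tP5": tP5,
        "vP3": vP3, "alpha": alpha, "ok1": ok1, "ok5": ok5,
        "t50_left": t50_left if okl else None,
        "t50_right": t50_right if okr else None,
    }


def find_characteristic_points(
    v: np.ndarray, t: np.ndarray, p1p5_fraction: float = 0.01, smooth: bool = True
) -> CharacteristicPoints:
    """Locate P1..P5 on a single positive lobe.

    The lobe is interpolated with a quintic spline; the peak is the root of
    the spline derivative bracketing the discrete maximum, the inflections
    are the sign changes of the spline second derivative nearest the peak,
    and onset/offset are the nearest crossings of ``p1p5_fraction * vP3``
    (default 1% of peak) walking outward from the peak.  Noisy lobes are
    lightly Savitzky-Golay smoothed first (see ``_auto_smooth``).

    Raises
    ------
    ExtractionError
        Degenerate input: no interior maximum, or no inflection on a side.
    """
    pts = _locate_points(v, t, p1p5_fraction, smooth)
    if pts["tP2"] is None or pts["tP4"] is None:
        raise ExtractionError("no inflection found on one side of the peak")
    return CharacteristicPoints(
        pts["tP1"], pts["tP2"], pts["tP3"], pts["tP4"], pts["tP5"], pts["vP3"]
    )


# --------------------------------------------------------------------------
# closed-form inversion


def _infl_exponents(sigma: float) -> tuple[float, float]:
    """Log-time offsets (from mu) of the two inflection points."""
    a = sigma * np.sqrt(0.25 * sigma**2 + 1.0)
    return -1.5 * sigma**2 - a, -1.5 * sigma**2 + a


def estimate_sigma(
    p: CharacteristicPoints,
    convention: str = "threshold",
    p1p5_fraction: float = 0.01,
) -> float:
    """Solve the onset/peak/offset time ratio for sigma.

    ``convention="threshold"`` (default): P1/P5 are the alpha-of-peak
    crossings (alpha = ``p1p5_fraction``), which for a lognormal sit at
    log-time -sigma^2 -/+ c·sigma with c = sqrt(-2 ln alpha).  The ratio
    (tP3-tP1)/(tP5-tP1) then equals 1/(e^(c sigma) + 1), inverted in closed
    form.

    ``convention="log3sigma"``: the classical form assuming onset/offset at
    log-time -/+ 3 sigma, solved by bracketed root-finding of
    (e^(-sigma^2) - e^(-3 sigma)) / (e^(3 sigma) - e^(-3 sigma)) = ratio
    on sigma in [0.01, 3].
    """
    ratio = (p.tP3 - p.tP1) / (p.tP5 - p.tP1)
    if not 0 < ratio < 1:
        raise ExtractionError(f"invalid point ratio {ratio}")
    if convention == "threshold":
        c = np.sqrt(-2.0 * np.log(p1p5_fraction))
        arg = 1.0 / ratio - 1.0
        if arg <= 1.0:  # sigma would be <= 0
            raise ExtractionError(f"point ratio {ratio} out of range")
        sigma = float(np.log(arg) / c)
        if sigma < 0.01:
            warnings.warn("sigma at/below lower bracket 0.01", stacklevel=2)
            sigma = max(sigma, 0.01)
        return sigma
    if convention == "log3sigma":

        def rhs(s: float) -> float:
            return (np.exp(-(s**2)) - np.exp(-3 * s)) / (
                np.exp(3 * s) - np.exp(-3 * s)
            )

        f = lambda s: rhs(s) - ratio
        if f(0.01) * f(3.0) > 0:
            raise ExtractionError(
                f"ratio {ratio} outside RHS range over sigma in [0.01, 3]"
            )
        return float(brentq(f, 0.01, 3.0, xtol=1e-8))
    raise ValueError(f"unknown convention {convention!r}")


def estimate_sigma_left(p: CharacteristicPoints, p1p5_fraction: float = 0.01) -> float:
    """Sigma from the left-side ratio (tP3 - tP1)/(tP3 - tP2).

    Uses only onset, first inflection and peak — the portion of the head
    lobe that the trunk lobe's overlap cannot mask — so it serves as the
    initial phase-1 estimate before model subtraction exposes the full lobe.
    """
    return _sigma_from_left_ratio(p.tP1, p.tP2, p.tP3, p1p5_fraction)


def estimate_mu_t0_D(
    p: CharacteristicPoints, sigma: float, check_consistency: bool = True
) -> tuple[float, float, float]:
    """Closed-form (mu, t0, D) from the characteristic points given sigma.

    mu from the inflection spacing, t0 from the peak location, D from the
    peak height:

        mu = ln[(tP4 - tP2) / (e^(-1.5 s^2 + s a) - e^(-1.5 s^2 - s a))],
             a = sqrt(0.25 s^2 + 1)
        t0 = tP3 - e^(mu - s^2)
        D  = sqrt(2 pi) s vP3 e^(mu - s^2 / 2)
    """
    if p.tP4 <= p.tP2:
        raise ExtractionError("inflection points out of order")
    y2, y4 = _infl_exponents(sigma)
    mu = float(np.log((p.tP4 - p.tP2) / (np.exp(y4) - np.exp(y2))))
    t0 = float(p.tP3 - np.exp(mu - sigma**2))
    D = float(_SQRT_2PI * sigma * p.vP3 * np.exp(mu - sigma**2 / 2.0))
    if check_consistency:
        c = LognormalComponent(D, t0, mu, sigma)
        model_peak = lognormal_value(p.tP3, c)
        if abs(model_peak - p.vP3) > 5e-3 * p.vP3:
            warnings.warn(
                f"peak-height consistency off by "
                f"{abs(model_peak - p.vP3) / p.vP3:.2%}",
                stacklevel=2,
            )
    return mu, t0, D


def _component_from_sigma_and_left(sigma, tP2, tP3, vP3) -> LognormalComponent:
    """Finish the inversion from sigma plus left inflection and peak."""
    y2, _ = _infl_exponents(sigma)
    mu = float(np.log((tP3 - tP2) / (np.exp(-(sigma**2)) - np.exp(y2))))
    t0 = float(tP3 - np.exp(mu - sigma**2))
    D = float(_SQRT_2PI * sigma * vP3 * np.exp(mu - sigma**2 / 2.0))
    return LognormalComponent(D, t0, mu, sigma)


def _sigma_from_left_ratio(tP1, tP2, tP3, p1p5_fraction) -> float:
    c = np.sqrt(-2.0 * np.log(p1p5_fraction))
    robs = (tP3 - tP1) / (tP3 - tP2)

    def f(s: float) -> float:
        y1 = -(s**2) - c * s
        y2, _ = _infl_exponents(s)
        e3 = np.exp(-(s**2))
        return (e3 - np.exp(y1)) / (e3 - np.exp(y2)) - robs

    if f(0.01) * f(3.0) > 0:
        raise ExtractionError(f"left-side point ratio {robs} outside invertible range")
    return float(brentq(f, 0.01, 3.0, xtol=1e-8))


def _sigma_from_halfmax_ratio(tP1, t50_left, tP3, p1p5_fraction) -> float:
    """Sigma from (tP3 - tP1)/(tP3 - t_halfmax,left); inflection-free, so it
    survives heavy truncation of the right side."""
    c01 = np.sqrt(-2.0 * np.log(p1p5_fraction))
    c50 = np.sqrt(2.0 * np.log(2.0))
    robs = (tP3 - tP1) / (tP3 - t50_left)

    def f(s: float) -> float:
        return (1.0 - np.exp(-c01 * s)) / (1.0 - np.exp(-c50 * s)) - robs

    if f(0.01) * f(3.0) > 0:
        raise ExtractionError(f"half-max ratio {robs} outside invertible range")
    return float(brentq(f, 0.01, 3.0, xtol=1e-8))


def _sigma_from_right_ratio(tP3, tP4, tP5, p1p5_fraction) -> float:
    """Sigma from (tP5 - tP3)/(tP4 - tP3): offset tail, second inflection
    and peak — the side of the trunk lobe the head lobe cannot mask."""
    c = np.sqrt(-2.0 * np.log(p1p5_fraction))
    robs = (tP5 - tP3) / (tP4 - tP3)

    def f(s: float) -> float:
        _, y4 = _infl_exponents(s)
        e3 = np.exp(-(s**2))
        return (np.exp(-(s**2) + c * s) - e3) / (np.exp(y4) - e3) - robs

    if f(0.01) * f(3.0) > 0:
        raise ExtractionError(f"right-side point ratio {robs} outside invertible range")
    return float(brentq(f, 0.01, 3.0, xtol=1e-8))


def _sigma_from_halfmax_right_ratio(tP3, tP4, t50_right) -> float:
    """Sigma from (t_halfmax,right - tP3)/(tP4 - tP3); survives an offset
    tail clipped by the segment boundary."""
    c50 = np.sqrt(2.0 * np.log(2.0))
    robs = (t50_right - tP3) / (tP4 - tP3)

    def f(s: float) -> float:
        _, y4 = _infl_exponents(s)
        e3 = np.exp(-(s**2))
        return (np.exp(-(s**2) + c50 * s) - e3) / (np.exp(y4) - e3) - robs

    if f(0.01) * f(3.0) > 0:
        raise ExtractionError(f"right half-max ratio {robs} outside invertible range")
    return float(brentq(f, 0.01, 3.0, xtol=1e-8))


def _component_from_sigma_and_right(sigma, tP3, tP4, vP3) -> LognormalComponent:
    _, y4 = _infl_exponents(sigma)
    mu = float(np.log((tP4 - tP3) / (np.exp(y4) - np.exp(-(sigma**2)))))
    t0 = float(tP3 - np.exp(mu - sigma**2))
    D = float(_SQRT_2PI * sigma * vP3 * np.exp(mu - sigma**2 / 2.0))
    return LognormalComponent(D, t0, mu, sigma)


def _component_from_halfmax(t50_left, tP3, t50_right, vP3) -> LognormalComponent:
    """Closed-form component from the peak and its two half-max crossings.

    For a lognormal, (t50R - tP3)/(tP3 - t50L) = e^(c sigma) with
    c = sqrt(2 ln 2), giving sigma directly; mu follows from the full width
    at half maximum and (t0, D) from the peak location and height.  All
    three points sit high on the lobe, so this estimator tolerates masked
    or clipped tails and noise floors.
    """
    c50 = np.sqrt(2.0 * np.log(2.0))
    ratio = (t50_right - tP3) / (tP3 - t50_left)
    if not np.isfinite(ratio) or ratio <= 0:
        raise ExtractionError(f"invalid half-max asymmetry ratio {ratio}")
    # near-symmetric lobes (ratio ~ 1, e.g. after heavy low-pass filtering)
    # sit in the lognormal's Gaussian limit where sigma is weakly
    # identified; clip to a moderate shape and let mu carry the width
    sigma = float(np.clip(np.log(max(ratio, 1.0 + 1e-9)) / c50, 0.08, 1.5))
    width = t50_right - t50_left
    mu = float(np.log(width)
               - np.log(np.exp(-(sigma**2) + c50 * sigma)
                        - np.exp(-(sigma**2) - c50 * sigma)))
    t0 = float(tP3 - np.exp(mu - sigma**2))
    D = float(_SQRT_2PI * sigma * vP3 * np.exp(mu - sigma**2 / 2.0))
    return LognormalComponent(D, t0, mu, sigma)


def _extract_component(
    v: np.ndarray,
    t: np.ndarray,
    p1p5_fraction: float,
    sigma_from: str = "threshold",
) -> LognormalComponent:
    """Point-based extraction of a single lognormal component from a lobe.

    ``sigma_from="threshold"`` requires the complete point set (full lobe).
    ``sigma_from="left"`` uses only the left side of the lobe — onset,
    half-max crossing, first inflection and peak — for a lobe whose right
    tail is masked by the other phase, trying the onset/inflection ratio
    first and the inflection-free half-max ratio as fallback.
    ``sigma_from="right"`` mirrors this for a lobe whose left side is
    masked (offset tail, second inflection, peak).
    """
    pts = _locate_points(v, t, p1p5_fraction)
    tP1, tP2, tP3, vP3 = pts["tP1"], pts["tP2"], pts["tP3"], pts["vP3"]
    tP4, tP5 = pts["tP4"], pts["tP5"]
    alpha = pts["alpha"]  # effective onset/offset fraction actually used
    if sigma_from == "left":
        sigma = None
        if tP2 is not None:
            try:
                sigma = _sigma_from_left_ratio(tP1, tP2, tP3, alpha)
            except ExtractionError:
                sigma = None
        if sigma is None and pts["t50_left"] is not None and pts["ok1"]:
            try:
                sigma = _sigma_from_halfmax_ratio(tP1, pts["t50_left"], tP3, alpha)
            except ExtractionError:
                sigma = None
        if sigma is None:
            if pts["t50_left"] is not None and pts["t50_right"] is not None:
                return _component_from_halfmax(
                    pts["t50_left"], tP3, pts["t50_right"], vP3
                )
            raise ExtractionError("left-side extraction failed (no usable points)")
        if tP2 is not None:
            return _component_from_sigma_and_left(sigma, tP2, tP3, vP3)
        # place the component from the onset/peak spacing alone
        c = np.sqrt(-2.0 * np.log(alpha))
        mu = float(np.log(tP3 - tP1)
                   - np.log(np.exp(-(sigma**2)) - np.exp(-(sigma**2) - c * sigma)))
        t0 = float(tP3 - np.exp(mu - sigma**2))
        D = float(_SQRT_2PI * sigma * vP3 * np.exp(mu - sigma**2 / 2.0))
        return LognormalComponent(D, t0, mu, sigma)
    if sigma_from == "right":
        if tP4 is None:
            raise ExtractionError("right-side extraction failed (no inflection)")
        sigma = None
        if pts["ok5"]:
            try:
                sigma = _sigma_from_right_ratio(tP3, tP4, tP5, alpha)
            except ExtractionError:
                sigma = None
        if sigma is None and pts["t50_right"] is not None:
            try:
                sigma = _sigma_from_halfmax_right_ratio(tP3, tP4, pts["t50_right"])
            except ExtractionError:
                sigma = None
        if sigma is None:
            if pts["t50_left"] is not None and pts["t50_right"] is not None:
                return _component_from_halfmax(
                    pts["t50_left"], tP3, pts["t50_right"], vP3
                )
            raise ExtractionError("right-side extraction failed (no usable points)")
        return _component_from_sigma_and_right(sigma, tP3, tP4, vP3)
    if tP2 is None or tP4 is None:
        raise ExtractionError("no inflection found on one side of the peak")
    if not (pts["ok1"] and pts["ok5"]):
        raise ExtractionError("lobe tail clipped: onset/offset crossing missing")
    cpts = CharacteristicPoints(tP1, tP2, tP3, tP4, tP5, vP3)
    sigma = estimate_sigma(cpts, "threshold", alpha)
    mu, t0, D = estimate_mu_t0_D(cpts, sigma, check_consistency=False)
    return LognormalComponent(D, t0, mu, sigma)


# --------------------------------------------------------------------------
# SNR


def snr(v: np.ndarray, v_hat: np.ndarray, t: np.ndarray) -> float:
    """Energy signal-to-noise ratio of a reconstruction, in dB.

    10 log10( int v^2 dt / int (v - v_hat)^2 dt ), trapezoidal integration,
    capped at +100 dB for (numerically) perfect reconstructions.
    """
    v = np.asarray(v, dtype=float)
    v_hat = np.asarray(v_hat, dtype=float)
    t = np.asarray(t, dtype=float)
    num = np.trapezoid(v**2, t)
    if num <= 0:
        raise ValueError("zero-energy signal: SNR undefined")
    den = np.trapezoid((v - v_hat) ** 2, t)
    if den <= num * 10.0 ** (-_SNR_CAP_DB / 10.0):
        return _SNR_CAP_DB
    return float(10.0 * np.log10(num / den))


# --------------------------------------------------------------------------
# two-phase fit


@dataclass
class SigmaLognormalFit:
    """Results of a two-phase sigma-lognormal fit of a turn's velocity profile.

    Phase 1 is the head lobe (positive), phase 2 the trunk lobe (negative in
    the profile; ``D2`` is stored positive and the model applies the minus
    sign).  ``t0`` values are reported on the time axis of the input grid.
    """

    phase1: LognormalComponent | None
    phase2: LognormalComponent | None
    time_grid: np.ndarray = field(repr=False, default=None)  # type: ignore
    v_measured: np.ndarray = field(repr=False, default=None)  # type: ignore
    v_reconstructed: np.ndarray = field(repr=False, default=None)  # type: ignore
    snr_db: float = np.nan
    snr_gate_db: float = 10.0
    converged: bool = False
    n_iter: int = 0
    failure_reason: str | None = None

    @property
    def qc_pass(self) -> bool:
        return bool(np.isfinite(self.snr_db) and self.snr_db > self.snr_gate_db)

    @property
    def success(self) -> bool:
        return self.phase1 is not None and self.phase2 is not None

    @property
    def params(self) -> dict:
        """The eight signature parameters (phase-wise D, t0, mu, sigma)."""
        out = {}
        for i, ph in ((1, self.phase1), (2, self.phase2)):
            if ph is None:
                out.update({f"D{i}": np.nan, f"t0{i}": np.nan,
                            f"mu{i}": np.nan, f"sigma{i}": np.nan})
            else:
                out.update({f"D{i}": ph.D, f"t0{i}": ph.t0,
                            f"mu{i}": ph.mu, f"sigma{i}": ph.sigma})
        return out

    def model(self, t: np.ndarray) -> np.ndarray:
        """Evaluate D1 L1(t) - D2 L2(t) on an arbitrary grid."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.phase1 is not None:
            out = out + lognormal_value(t, self.phase1)
        if self.phase2 is not None:
            out = out - lognormal_value(t, self.phase2)
        return out

    def summary(self) -> str:
        lines = ["Two-phase sigma-lognormal fit", "=" * 45]
        lines.append(f"{'':10s}{'phase 1 (head)':>16s}{'phase 2 (trunk)':>18s}")
        rows = [
            ("D [deg]", "D"),
            ("t0 [s]", "t0"),
            ("mu [log-s]", "mu"),
            ("sigma [-]", "sigma"),
        ]
        for label, attr in rows:
            v1 = getattr(self.phase1, attr) if self.phase1 else np.nan
            v2 = getattr(self.phase2, attr) if self.phase2 else np.nan
            lines.append(f"{label:10s}{v1:16.4f}{v2:18.4f}")
        for label, attr in [("tbar [s]", "tbar"), ("s [s]", "s_resp"),
                            ("vmax [d/s]", "vmax")]:
            v1 = getattr(self.phase1, attr) if self.phase1 else np.nan
            v2 = getattr(self.phase2, attr) if self.phase2 else np.nan
            lines.append(f"{label:10s}{v1:16.4f}{v2:18.4f}")
        lines.append("-" * 45)
        lines.append(
            f"SNR: {self.snr_db:.1f} dB (gate {self.snr_gate_db:.0f} dB) "
            f"-> QC {'pass' if self.qc_pass else 'FAIL'}"
        )
        lines.append(
            f"converged: {self.converged} after {self.n_iter} iterations"
        )
        if self.failure_reason:
            lines.append(f"failure: {self.failure_reason}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs reconstructed profile (diagnostics)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time_grid, self.v_measured, label="measured")
        ax.plot(self.time_grid, self.v_reconstructed, "--", label="reconstructed")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("axial relative angular velocity [deg/s]")
        ax.legend()
        return ax


class TurnSignatureModel:
    """Sigma-lognormal model of a turn-direction-normalized axial velocity
    profile, statsmodels-style.

    Parameters
    ----------
    v_axial : array
        Axial head-relative-to-trunk angular velocity over the turn segment,
        deg/s, first (head) lobe positive.
    t : array
        Sample times, seconds.
    snr_gate_db : float
        Quality gate on the reconstruction SNR.
    p1p5_fraction : float
        Onset/offset threshold as a fraction of the lobe peak.
    """

    def __init__(
        self,
        v_axial: np.ndarray,
        t: np.ndarray,
        snr_gate_db: float = 10.0,
        p1p5_fraction: float = 0.01,
    ) -> None:
        self.v = np.asarray(v_axial, dtype=float)
        self.t = np.asarray(t, dtype=float)
        if self.v.shape != self.t.shape:
            raise ValueError("v_axial and t shapes differ")
        if not 0 < p1p5_fraction < 0.5:
            raise ValueError("p1p5_fraction must lie in (0, 0.5)")
        self.snr_gate_db = float(snr_gate_db)
        self.p1p5_fraction = float(p1p5_fraction)

    # -- fitting -----------------------------------------------------------

    def _split_index(self) -> int:
        v = self.v
        imax = int(np.argmax(v))
        imin = int(np.argmin(v))
        if v[imax] <= 0 or v[imin] >= 0 or imax >= imin:
            raise ExtractionError("fewer than two opposite-sign lobes detected")
        seg = v[imax : imin + 1]
        off = int(np.argmax(seg <= 0))
        if seg[off] > 0:
            raise ExtractionError("no zero crossing between the lobes")
        return imax + off

    def fit(
        self, max_iter: int = 60, damping: float = 0.5, tol: float = 1e-10
    ) -> SigmaLognormalFit:
        """Fit both phases by point-based extraction with damped alternating
        model subtraction.

        Initial estimates use the unmasked side of each lobe: phase 1 from
        the left side of the positive lobe (its offset tail is masked by
        phase 2), phase 2 from the right side of the negated negative lobe.
        Each iteration then subtracts the current model of the other phase
        and re-extracts the full, unmasked lobe with the threshold-based
        estimator; updates are damped to stabilise the fixed-point
        iteration, and the lowest-residual pair seen is returned.  On
        noiseless data the exact parameters are a fixed point.
        """
        v, t = self.v, self.t

        def fail(reason):
            return SigmaLognormalFit(
                None, None, t, v, np.zeros_like(v),
                snr_db=np.nan, snr_gate_db=self.snr_gate_db,
                failure_reason=reason,
            )

        try:
            iz = self._split_index()
        except ExtractionError as exc:
            return fail(str(exc))

        arr = lambda c: np.array([c.D, c.t0, c.mu, c.sigma])
        comp = lambda a: LognormalComponent(*a)

        c50 = np.sqrt(2.0 * np.log(2.0))

        def robust_extract(sig, tt, *modes):
            """Per-lobe estimate required to reproduce its lobe's peak and
            half-max width within a factor 2 (guards against degenerate
            collapse); the half-max construction, which matches peak and
            width by construction, is the final fallback."""
            pts = _locate_points(sig, tt, self.p1p5_fraction)
            i = int(np.argmax(sig))
            peak = sig[i]
            obs_width = (
                pts["t50_right"] - pts["t50_left"]
                if pts["t50_left"] is not None and pts["t50_right"] is not None
                else None
            )

            def consistent(c):
                pred = lognormal_value(tt[i], c)
                if peak <= 0 or not 0.5 * peak <= pred <= 2.0 * peak:
                    raise ExtractionError("component inconsistent with lobe peak")
                if obs_width is not None:
                    mw = np.exp(c.mu) * (
                        np.exp(-c.sigma**2 + c50 * c.sigma)
                        - np.exp(-c.sigma**2 - c50 * c.sigma)
                    )
                    if not 0.5 * obs_width <= mw <= 2.0 * obs_width:
                        raise ExtractionError("component inconsistent with lobe width")
                return c

            for mode in modes:
                try:
                    return consistent(
                        _extract_component(sig, tt, self.p1p5_fraction, mode)
                    )
                except (ExtractionError, ValueError):
                    continue
            if obs_width is None:
                raise ExtractionError("half-max crossings unavailable")
            return consistent(
                _component_from_halfmax(
                    pts["t50_left"], pts["tP3"], pts["t50_right"], pts["vP3"]
                )
            )

        p1 = p2 = None
        try:
            p1 = robust_extract(v[: iz + 1], t[: iz + 1], "left")
        except (ExtractionError, ValueError):
            pass
        try:
            p2 = robust_extract(-v[iz:], t[iz:], "right")
        except (ExtractionError, ValueError):
            pass
        if p1 is None and p2 is None:
            return fail("initial extraction failed for both phases")
        # complete a missing side by subtracting the other phase's model
        try:
            if p1 is None:
                v1 = v + lognormal_value(t, p2)
                p1 = robust_extract(v1, t, "left")
            if p2 is None:
                v2 = -(v - lognormal_value(t, p1))
                p2 = robust_extract(v2, t, "right")
        except (ExtractionError, ValueError) as exc:
            return fail(f"could not initialise both phases: {exc}")
        x1, x2 = arr(p1), arr(p2)

        def residual(a1, a2):
            r = v - lognormal_value(t, comp(a1)) + lognormal_value(t, comp(a2))
            return float(np.sum(r * r))

        best = (x1.copy(), x2.copy())
        best_sse = residual(x1, x2)
        converged = False
        n_done = 0
        for it in range(max_iter):
            n_done = it + 1
            x1_old = x1.copy()
            updated = False
            try:
                v2 = -(v - lognormal_value(t, comp(x1)))
                p2n = arr(robust_extract(v2, t, "threshold", "right"))
                x2 = damping * p2n + (1 - damping) * x2
                updated = True
            except (ExtractionError, ValueError):
                pass
            try:
                v1 = v + lognormal_value(t, comp(x2))
                p1n = arr(robust_extract(v1, t, "threshold", "left"))
                x1 = damping * p1n + (1 - damping) * x1
                updated = True
            except (ExtractionError, ValueError):
                pass
            if not updated:
                break  # keep the best pair seen so far
            sse = residual(x1, x2)
            if sse < best_sse:
                best_sse = sse
                best = (x1.copy(), x2.copy())
            if it > 2 and np.max(np.abs(x1 - x1_old)) < tol:
                converged = True
                break

        phase1, phase2 = comp(best[0]), comp(best[1])
        v_hat = lognormal_value(t, phase1) - lognormal_value(t, phase2)
        fit_snr = snr(v, v_hat, t)
        return SigmaLognormalFit(
            phase1, phase2, t, v, v_hat,
            snr_db=fit_snr, snr_gate_db=self.snr_gate_db,
            converged=converged, n_iter=n_done,
        )


def fit_two_phase(
    v_axial: np.ndarray,
    t: np.ndarray,
    snr_gate_db: float = 10.0,
    p1p5_fraction: float = 0.01,
) -> SigmaLognormalFit:
    """Functional wrapper around ``TurnSignatureModel(...).fit()``."""
    return TurnSignatureModel(v_axial, t, snr_gate_db, p1p5_fraction).fit()
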