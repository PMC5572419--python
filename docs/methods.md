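# Methods

## Model

The axial head-relative-to-trunk angular-velocity profile of a 180° turn
is modelled as the difference of two lognormal impulse responses,

    v(t) = D1 Λ(t; t01, μ1, σ1²) − D2 Λ(t; t02, μ2, σ2²),
    Λ(t; t0, μ, σ²) = exp(−(ln(t−t0) − μ)² / 2σ²) / (σ (t−t0) √2π),  t > t0,

the kinematic-theory description of two neuromuscular commands: the head
engages first (positive lobe), the trunk catches up (negative lobe). Each
component carries a command amplitude D (degrees — the area under its
velocity lobe), a command occurrence time t0 (seconds), a log time delay μ
and a log response time σ. Derived per phase:

    t̄   = t0 + e^(μ + σ²/2)             (mean response time, s)
    s    = (t̄ − t0) √(e^(σ²) − 1)       (response-time spread, s)
    Vmax = D e^(−μ + σ²/2) / (σ √2π)    (peak lobe velocity, deg/s)

Assumptions: the turn contains exactly two dominant opposite-sign lobes;
the rotation is yaw-dominated so a single axial projection carries the
signature; head and trunk realign after the turn (D1 ≈ D2) in healthy
turning, though the model does not require it.

## Pipeline

1. **Alignment.** Each sensor stream is right-multiplied by the conjugate
   of its neutral-pose mean quaternion (normalized arithmetic mean of
   sign-aligned quaternions over the annotated standing window, ≥ 0.5 s).
   This cancels any constant sensor-mounting offset exactly and expresses
   each segment as rotation-from-neutral; window dispersion > 5° logs a
   warning. The axial axis is the longitudinal (vertical) axis of the
   neutral stance.
2. **Relative orientation.** q_rel = q*_trunk ⊗ q_head, kept
   hemisphere-continuous (consecutive quaternion dot products ≥ 0).
3. **Filtering.** The relative rotation is decomposed into a *continuous
   signed* axis-angle branch — when the rotation passes near identity the
   branch (θ, û) → (−θ, −û) is chosen for continuity, since both encode
   the same rotation — and the rotation vector θ·û is filtered
   component-wise with a zero-phase (forward-backward) 4th-order
   Butterworth low-pass, then recomposed. The unsigned decomposition folds
   at identity and would spike the finite-difference rates whenever
   pre-turn gait crosstalk oscillates about zero. Zero-phase application
   preserves the timing parameters (no group delay); the effective
   magnitude response is the square of the one-pass filter (−6 dB at the
   cutoff). Default cutoff 1.5 Hz at 60 Hz sampling; a residual-analysis
   utility (smallest cutoff with RMS(raw−filtered) ≤ 2°, aggregated over
   trials as mean + 1.645·SD to cover 95% of cases, candidates
   0.5–6 Hz in 0.1 Hz steps) supports recalibration.
4. **Angular velocity.** ω = θ̇û + û̇ sinθ + (û×û̇)(1−cosθ), with central
   finite differences (one-sided at the ends); the axial projection in
   deg/s, sign-normalized so the first (head) lobe is positive, is the
   profile handed to the model. The axial relative angle (rotation vector
   projected on the axial axis) gives H2Tmax over the turn segment.
5. **Segmentation.** Turn boundaries come from the events file (annotated
   turn_start/turn_end, or heel strikes bracketing annotated
   misalignment/realignment times). A misalignment-onset helper (earliest
   time the maximum pairwise head/trunk/pelvis axial angle exceeds 5°
   sustained 0.2 s) assists annotation; it never segments silently.

## Parameter estimation

Characteristic points of each lobe — onset P1, first inflection P2, peak
P3, second inflection P4, offset P5 — are located on a quintic
interpolating spline: the peak from the spline-derivative root bracketing
the discrete maximum, inflections from sign changes of the spline second
derivative nearest the peak (Brent-refined), and onset/offset as the
nearest crossings of a fraction α of the peak (default 1%), walking
outward from the peak so baseline wiggle cannot trigger them early. For a
lognormal, the α-crossings sit at log-time −σ² ∓ cσ with c = √(−2 ln α),
which gives the closed-form inversion chain actually used:

    (tP3−tP1)/(tP5−tP1) = 1/(e^(cσ)+1)                  → σ
    μ  = ln[(tP4−tP2)/(e^(−1.5σ²+σa) − e^(−1.5σ²−σa))],  a = √(0.25σ²+1)
    t0 = tP3 − e^(μ−σ²)
    D  = √2π σ vP3 e^(μ−σ²/2)

The classical convention that places onset/offset at log-time ∓3σ is
available as an alternative (`estimate_sigma(..., "log3sigma")`); feeding
α-crossing ratios into that convention would bias σ by ~20%, so the
threshold-consistent form is the default.

**Two-phase separation.** The lobes overlap, masking the head lobe's tail
and the trunk lobe's onset. The fit therefore (i) forms initial estimates
from the *unmasked* side of each lobe — σ from the left-side ratio
(tP3−tP1)/(tP3−tP2) for phase 1 and the mirrored right-side ratio for
phase 2, with a half-max-based closed form
(σ = ln[(t50R−tP3)/(tP3−t50L)]/√(2 ln 2), μ from the FWHM, D/t0 from the
peak) as a guaranteed fallback — then (ii) alternates: subtract the
current model of one phase, re-extract the other from its now-complete
lobe, with updates damped by 0.5 to stabilise the fixed point, for up to
60 iterations. Every extracted component must reproduce its lobe's peak
height and half-max width within a factor 2, otherwise the update is
rejected; the lowest-residual pair seen is returned. On noiseless input
the true parameters are a fixed point of this map and are recovered to
machine-level accuracy at 240 Hz and within fractions of a percent at
60 Hz.

**Noise handling.** Points are located on a lightly Savitzky-Golay
pre-smoothed copy when the high-frequency residual exceeds 0.1% of the
peak (cubic, window ≤ 0.25 s and ≤ 0.6 lobe-FWHM); clean signals are
analysed exactly as sampled. On noisy lobes the effective onset/offset
fraction is raised to clear 3× the estimated post-smoothing noise floor
(capped at 0.25); the σ inversion is parametric in the fraction, so
estimates remain consistent.

**Quality gate.** SNR = 10·log10(∫v² dt / ∫(v−v̂)² dt), trapezoidal,
capped at 100 dB; trials at or below 10 dB (configurable) fail QC and are
excluded from the reliability analysis by default.

## Statistics

Pace robustness: per-participant, per-pace metric means compared with a
two-sided Wilcoxon signed-rank test (zero differences discarded; exact
null for ≤ 25 tie-free pairs, normal approximation with continuity
correction otherwise; scipy's implementation, verified against full
sign-assignment enumeration in the tests). Reliability: ICC(2,k) — two-way
random effects, absolute agreement, average measures — from the
participants × trials ANOVA mean squares, with the McGraw–Wong F-based 95%
interval (Satterthwaite degrees of freedom) and SEM = SD·√(1−ICC); rows
with missing trials are dropped listwise. Interpretation bands: poor
(< 0.50), moderate [0.50, 0.75), good [0.75, 0.90), excellent
[0.90, 1.00]; negative estimates are poor. The implementation is
cross-checked against pingouin's ICC(A,k) to 1e-10 in the tests.

## Synthetic trials

The generator emulates the study conditions: 60 Hz streams over a 12 s
trial; neutral standing (0.2–1.2 s); gait from 1.5 s at 1.8 Hz cadence
with 2°/1° roll/pitch sinusoids; a raised-cosine 180° trunk yaw ramp of
2.2 s starting at 6 s (×0.75 duration at fast pace); head yaw = trunk yaw
plus the integral of the programmed two-lognormal profile (defaults
D1 = D2 = 25°, t01 = 0.1 s, t02 = 0.6 s, μ = −0.3/0.1, σ = 0.30/0.25,
giving response times s ≈ 0.24–0.29 s and peak relative angles near 23° —
the dispersion ranges reported for healthy older adults); a pelvis track
lagging the trunk by 0.15 s; constant random mounting offsets (≤ ~8°) per
sensor; orientation noise as small random rotations (SD 0.3°, preserving
unit norm); an accelerometer channel with gravity, Gaussian heel-strike
bursts (3 m/s², 50 ms) and 0.3 m/s² noise; a gyroscope channel with the
trunk yaw rate plus 0.02 rad/s noise. Cohorts draw participant-level
signature parameters (between-subject SD 6° on D, proportionally scaled
on the timing parameters) and trial-level jitter (within-subject SD 2°),
all from a single seed.

What the generator does *not* emulate: soft-tissue artifact, magnetic
disturbance of the AHRS fusion, stride-to-stride timing variability,
non-lognormal velocity profiles, and the manual segmentation variability
of real trials. Passing tests therefore demonstrate the correctness of
the computational chain and its statistical behaviour under the stated
conditions, not clinical validity on human recordings.

## Behaviour under the default conditions

With the defaults above, a 16-participant × 4-trial cohort yields ~95%
QC retention and a median reconstruction SNR near 21 dB. The 1.5 Hz
filter noticeably symmetrizes the velocity lobes, pushing fits toward the
lognormal's Gaussian limit where (μ, σ, t0) are only weakly identified —
command times can come out strongly negative with large dispersion while
the reconstruction stays excellent. Amplitude-like quantities (H2Tmax,
D1, D2) remain well-determined and highly reliable; timing parameters are
markedly less reliable. This asymmetry is a property of the method on
filtered data, and mirrors what is observed on real recordings.

## Numerical choices and limitations

- Time is float seconds from recording start; quaternions scalar-first;
  gaps < 3 samples are slerp-interpolated on load, larger gaps are errors.
- θ ≈ 0 axis convention: carry the previous axis forward (axial z at the
  first sample).
- Root-finding uses Brent's method (σ bracket [0.01, 3], tolerance 1e-8);
  the fixed-point iteration stops at parameter changes < 1e-10 or 60
  iterations.
- Degenerate inputs (monotone profile, single lobe, all-zero signal)
  yield explicit failure flags, never silent numbers; failed trials keep
  their H2Tmax and traditional metrics.
- No nonlinear least-squares polish is applied after the point-based
  estimation: the estimator chain stays closed-form throughout, and its
  output is what the reliability statistics characterize.
- Heavily overlapping lobes (command separation ≲ 0.3 s) or strongly
  non-lognormal profiles bias the point-based estimates; such trials
  surface as low SNR and are caught by the quality gate.
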