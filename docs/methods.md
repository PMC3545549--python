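# Methods

This document describes the estimation method implemented by `swimvel`:
how the instantaneous forward velocity of a front-crawl swimmer is
recovered from a single sacrum-worn inertial measurement unit (IMU),
how it is validated against a tethered speedometer, and which numerical
and design choices the implementation makes.

## Problem and coordinate frames

A 3D accelerometer + 3D gyroscope unit is fixed to the swimmer's sacrum.
The goal is the swimmer's instantaneous forward velocity over a 25 m
trial, accurate at the centimetre-per-second scale, without any external
tracking during the trial.

Two frames are used throughout:

- **Sensor frame (SF)** — the IMU's own axes; all raw measurements live
  here.
- **Global frame (GF)** — pool-fixed: `X` lateral, `Y` the swimming
  direction, `Z` up. Gravity is `(0, 0, −g)` with `g = 9.81 m s⁻²`.

Orientation is the sensor-to-global rotation, stored as a scalar-first
unit quaternion `q = (w, x, y, z)`; a sensor-frame vector maps to the
global frame by conjugation, `v_GF = q ⊗ v_SF ⊗ q⁻¹`.

## Pipeline

### 1. Initial pose from the static start

The trial must begin with the swimmer motionless (floating or braced)
for at least the static window (0.5 s by default). Over that window the
accelerometer reads only the gravity reaction, so its mean direction is
global "up" expressed in the sensor frame. The initial quaternion `q₀`
is the smallest rotation taking that mean onto `(0, 0, 1)`; its axis is
horizontal by construction. The window is validated two ways: the mean
norm must be within 15 % of `g`, and the sample-to-sample norm SD below
5 % of `g` (otherwise the start was not static and the run aborts).

Heading is unobservable from gravity alone; the method never needs it,
because the forward direction is re-estimated each stroke cycle from the
roll axis (step 4).

### 2. Gyroscope strapdown

Orientation is propagated one sample at a time with body-frame rotation
increments: `q_t = q_{t−1} ⊗ Δq_t` where `Δq_t` is the axis–angle
quaternion of `ω_t / f` (rate times sample period, 500 Hz). This is
exact for piecewise-constant rates; the first-order error of the
axis–angle exponential is zero, leaving only the piecewise-constant
approximation (tested: halving the step changes a 2 s integration by
less than the commutation bound). Quaternions are renormalized to unit
length to stop round-off accumulation.

Uncompensated gyroscope bias and noise make this orientation drift at
roughly the bias magnitude (degrees per second integrate to degrees);
step 4 removes the component that matters.

### 3. Stroke-cycle detection

Front crawl rolls the body about the longitudinal axis once per stroke
cycle. The global-frame forward (Y) component of the rotated angular
velocity is low-pass filtered (4th-order zero-phase Butterworth, 3 Hz
cutoff) and cycle boundaries are taken at its upward zero crossings,
with a 0.4 s refractory period and an amplitude gate at 70 % of the
median positive-lobe peak to reject ripples. Cycle lengths are
constrained to a physiological band (0.4–5 s).

### 4. Per-cycle roll-constraint orientation correction

The biomechanical constraint: averaged over one stroke cycle, the body's
dominant rotation axis is the swimming direction `Y`. For each detected
cycle the principal axis `p` of the global-frame angular-velocity
samples is extracted by PCA (leading eigenvector of the covariance,
signed toward `+Y`). Any deviation of `p` from `Y` is attributed to
accumulated orientation drift, and removed by a global-frame (left)
corrective rotation about `u = p × Y` of angle `Δθ = arccos(p·Y)`,
applied as a **linear ramp** across the cycle (zero at the cycle start,
full at its end) so no orientation discontinuity enters the
differentiated quantities.

Corrections accumulate sequentially: cycle `k`'s principal axis is
measured after the corrections of cycles `1..k−1` are applied, each
cycle's full correction is held constant into the next cycle, and the
correction is held after the last boundary. The first ramp starts at
sample 0 (not at the first boundary), because drift accrues from the
start of integration and an uncorrected lead-in leaks gravity into the
forward acceleration there.

The correction is applied **once**. Iterating it to a fixed point was
tried and rejected: the per-cycle principal axis carries a ≈1° deviation
from genuine (non-drift) pitch/yaw body motion, so iterations beyond the
first chase that floor and random-walk the orientation. The operator is
still contractive — a second application changes the result less than
the first — and that property is tested.

Known blind spot: the component of gyroscope bias along the roll (`Y`)
axis commutes with the constraint and is structurally unobservable. It
is also harmless here — a residual rotation about `Y` does not change
the `Y` component of the rotated specific force, so the forward velocity
is unaffected.

### 5. Forward acceleration and integration

The sensor-frame specific force is rotated to the global frame with the
corrected orientation; subtracting the gravity reaction `(0, 0, g)`
leaves body acceleration, whose `Y` component is the forward
acceleration. It is integrated to velocity by the trapezoidal rule
(exact for the piecewise-linear acceleration model, zero initial
velocity).

### 6. Drift segmentation (GMA)

Residual orientation error and accelerometer bias leave a slow drift in
the integrated velocity whose character changes when the movement's
statistics change. The trial is segmented by a Geometric Moving Average
(exponentially weighted) variance tracker on the forward acceleration:
with forgetting factor `λ`, the tracked mean and variance follow
`m_t = λ m_{t−1} + (1−λ) a_t` and
`s²_t = λ s²_{t−1} + (1−λ)(a_t − m_t)²`. A segment boundary is declared
when `s²_t` departs from the segment's frozen reference variance by more
than a fraction (0.20) of the trial's overall variance, after a burn-in
and guard interval of one filter memory `1/(1−λ)`. Segments shorter
than one median cycle are merged leftward.

Default `λ = 0.9985` (≈1.3 s memory at 500 Hz — about one stroke cycle).
A substantially shorter memory makes the tracked variance follow the
intra-cycle oscillation of the forward acceleration itself and the
detector chatters; at 1.3 s the filter attenuates the oscillation at
twice the stroke rate to ≲0.14 while still localizing a genuine variance
step within ≈120 samples.

### 7. Per-segment trend and anchored de-drifting

Within each segment, per-cycle maxima and minima of the integrated
velocity are interpolated by shape-preserving monotone cubics (PCHIP;
no overshoot beyond the knots), and the drift trend is the average of
the upper and lower envelopes. Segments containing fewer than two
cycles cannot be fitted; a leading or trailing cycle-less segment
inherits the nearest fitted segment's trend *edge value* (a constant),
which avoids the bias a segment-mean fallback would introduce where the
true velocity ramps from zero.

The trend is subtracted and the result anchored so its time average
equals the trial mean velocity `pool length / duration` — the only
external information used.

Finally, a **standing-start constraint**: the trial starts motionless,
so the anchored velocity at sample 0 must be zero. Over the leading
cycle-less region (before the first fitted segment) a one-parameter
quadratic adjustment `γ(1 − (t/t_e)²)` (made mean-free, so the anchor is
preserved to 1e−9) is subtracted with `γ` chosen to zero the first
sample. The quadratic shape matches the drift physics: orientation
error ramping over the lead-in ⇒ linearly growing gravity leak ⇒
quadratic velocity drift. Without it, lead-in drift has no envelope to
correct it and leaks through the anchoring constant into the whole
trial as a cycle-mean bias of several cm/s.

## Validation against the tethered reference

The reference device pays out a cord from a pulley ≈0.72 m above the
water, sampled at 100 Hz. Cord length `L` maps to horizontal
displacement `x = √(L² − h²)` (parallax correction); velocity is its
centered finite difference. For comparison, the 500 Hz estimate is
decimated to 100 Hz with a polyphase anti-aliasing filter, aligned by
normalized cross-correlation (peak required ≥ 0.3), and summarized by:

- **Bland–Altman** on paired cycle means (bias, precision = SD of the
  differences, 95 % limits of agreement, a Pearson screen of
  difference-vs-mean heteroscedasticity), in cm s⁻¹;
- **Spearman rank correlation** of the cycle means;
- **nPVI** — normalized pairwise variability index,
  `100 · mean(|r−e| / ((r+e)/2))` over paired cycle means;
- **instantaneous errors** — RMS and maximum of the sample-wise
  difference (cm s⁻¹) and the relative error at the maximum;
- **IVV** — intra-cyclic velocity variation, the stroke-frequency-
  weighted RMS of within-cycle deviations over the weighted mean, in %.

## Simulator

`swimvel.simulator` generates fully controlled trials for testing:
a quasi-periodic forward velocity (per-regime mean, sinusoidal
intra-cycle oscillation, smooth push-off ramp after a 1.5 s motionless
lead-in), body roll at the stroke rate (45° amplitude) with small
low-pass-filtered pitch/yaw jitter (0.03 rad RMS), and small vertical /
lateral bobbing accelerations. The gyroscope signal is derived by exact
strapdown inversion of the orientation trajectory (`Δq = q_{t−1}⁻¹ ⊗
q_t`), so with disturbances zeroed the generator and the estimator's raw
chain are exact adjoints. Sensor imperfections — constant (optionally
ramping) gyro bias, white rate noise, accelerometer bias and noise — are
typical of a calibrated consumer MEMS unit. The tethered reference is
generated from the exact cord-length geometry. A single integer seed
makes every trial bit-reproducible; eight presets (`elite_t1..t4`,
`recreational_t1..t4`) span 70–100 % of typical best paces for the two
groups.

One simulator property worth knowing: with sensor noise zeroed but
pitch/yaw jitter retained, the raw chain is still exact, yet the
roll-constraint correction injects the jitter's principal-axis deviation
(a few cm/s full-pipeline RMS). That is a property of the biomechanical
constraint — real pitch/yaw motion is indistinguishable from drift at
the per-cycle level — not an implementation error.

## Parameter summary

| Parameter | Default | Where | Rationale |
|---|---|---|---|
| Sampling rate (IMU) | 500 Hz | `ImuRecording.f` | typical research-grade logging rate |
| Gravity | 9.81 m s⁻² | `RunConfig.gravity` | standard value |
| Static window | 0.5 s | `RunConfig.static_window_s` | long enough to average accelerometer noise |
| Static norm SD limit | 5 % of g | `RunConfig.static_sd_limit_g` | rejects non-static starts |
| Cycle filter cutoff | 3 Hz | `RunConfig.cycle_cutoff_hz` | stroke rates are 0.5–1 Hz; passes the fundamental, kills noise |
| Cycle refractory | 0.4 s | `RunConfig.cycle_refractory_s` | below any physiological cycle period |
| Cycle length bounds | 0.4–5 s | `CycleSet` | physiological band |
| GMA forgetting factor | 0.9985 | `DEFAULT_LAMBDA` | ≈1 stroke cycle of memory; see step 6 |
| GMA threshold | 0.20 × Var(a) | `DEFAULT_THRESHOLD` | step-detection vs chatter trade-off |
| Min segment | median cycle length | pipeline | segments shorter than a cycle cannot carry an envelope |
| Comparison rate | 100 Hz | `RunConfig.comparison_rate` | the reference's native rate |
| Alignment search | ±2 s, peak ≥ 0.3 | `RunConfig.max_align_lag_s` | start-trigger offsets are < 2 s |
| Pulley height | 0.72 m | `ReferenceRecording` | typical starting-block mounting |

## Numerical choices

- Trapezoidal integration (`scipy.integrate.cumulative_trapezoid`):
  exact for linear acceleration between samples, the natural pairing
  with sampled data.
- Zero-phase filtering (`sosfiltfilt`) everywhere a boundary timing is
  read off a filtered signal — phase lag would shift cycle boundaries.
- PCHIP envelopes: shape-preserving; a cubic spline through velocity
  extrema overshoots and invents drift between knots.
- PCA via `numpy.linalg.eigh` on the 3×3 angular-velocity covariance:
  symmetric eigensolver, deterministic up to sign (resolved toward +Y).
- Polyphase resampling (`resample_poly`) for the 500→100 Hz comparison:
  anti-aliased, linear-phase, edge-padded by line extension.

## Limitations

- **Standing start required.** Both the initial pose and the
  standing-start detrending constraint assume a motionless lead-in; a
  flying start voids both (the pipeline rejects non-static starts).
- **Roll-axis gyro bias is unobservable** to the roll constraint (it
  commutes with the constraint); it is also harmless to the forward
  velocity, but orientation output should not be trusted about that
  axis.
- **Constraint floor from real pitch/yaw motion.** The per-cycle
  principal axis deviates ≈1° from the forward direction due to genuine
  body motion; drift below that scale per cycle cannot be separated
  from motion. This is why the correction is applied once, not
  iterated.
- **Occasional GMA over-segmentation.** On unlucky noise seeds the
  variance tracker can emit a spurious mid-cycle boundary; the
  per-segment envelope then kinks inside one cycle and that cycle's
  mean can be off by tens of cm/s while the rest of the trial is
  unaffected. Inspect `result.segments` when a single cycle looks
  anomalous; raising the GMA threshold for that trial is the remedy.
- **Mean-velocity anchor.** The absolute level relies on pool length /
  trial duration; timing or distance errors translate directly into a
  velocity bias (e.g. quoting 25 m for a trial whose ramped start
  covers 24 m biases the mean by several cm/s over 18 s).
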