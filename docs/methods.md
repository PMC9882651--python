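# Methods

This note documents the models, estimators, and numerical choices behind
`headstats`, and what the synthetic generator does and does not emulate.

## Frames and conventions

* World frame: right-handed, Z up; gravity `g_world = (0, 0, -9.81)` m/s².
* Head frame: X nasal-occipital (+ forward), Y interaural (+ left),
  Z dorsal-ventral (+ up).  The anatomical reference is Reid's baseline
  (canthus-to-meatus line), held perpendicular to gravity during the
  static calibration segment.
* Angles: intrinsic yaw–pitch–roll (Z–Y′–X″) decomposition of the head
  attitude.  Positive pitch = upward (extension), so the common downward
  (ground-looking) pitch is negative; positive roll = left-ear-down.
  Samples with |pitch| > 89.9° are flagged gimbal-adjacent.
* Stored quaternions are Hamilton, scalar-first, and encode the passive
  world→sensor (after alignment, world→head) coordinate transform.

These conventions are written into every exported file header.

## Sensor-to-head calibration

The protocol: 15 s static (Reid's baseline horizontal), five nods
(pitch), five shakes (yaw); nod/shake-only re-calibrations roughly every
30 minutes; a full block again at the end.

**Axis rotation.**  Both gyro windows are zero-phase low-pass filtered
(4th-order Butterworth, 2.5 Hz — the movements live at ~0.5 Hz, so this
only removes sensor noise; for a single-axis movement the filter leaves
the rotation axis exactly unchanged).  Each movement's axis is the first
principal direction of its angular-velocity sample cloud (eigenvector of
the raw second-moment matrix — the movements are oscillatory, so no mean
is removed).  Isotropic gyro noise adds a multiple of the identity to the
second moment and therefore does not bias the principal direction.  Signs
are fixed by positive projection on the nominal sensor axis, which
assumes the sensor is mounted within 90° of the head axes.  The pitch
axis is primary: the yaw axis is orthogonalized against it, the third
axis completes a right-handed triad, and the angle between the raw and
orthogonalized yaw axes is reported as a residual.  Half a second is
trimmed from each window edge so entry/exit transients cannot leak in.

With the five-nod protocol (±20° at 0.5 Hz, 10 s at 62.5 Hz) the axis
estimate is information-limited at σ_gyro/‖ω‖₂ ≈ 0.15° per degree of
freedom; at 0.05 rad/s gyro noise the composed recovery error is ~0.24°
on average with a 99th percentile near 0.5°.  Recovery accuracy is
therefore validated as a Monte-Carlo mean, not per draw.

**Reid pitch offset.**  The time-averaged static-segment acceleration is
taken as the gravity direction (its norm must be within 20% of 9.81 m/s²;
excess in-window variance is logged, not fatal).  After the axis
rotation, the pitch rotation that maps this direction to head −Z
completes the alignment: `R_sensor_head = R_y(−φ) · R_axes`.
Re-calibration blocks have no static segment, so the most recent offset
is carried forward and only the axis rotation is re-estimated; each
inter-calibration span uses the alignment from the block at its start,
and a failed block falls back to the previous span's alignment (logged).

## Pre-processing

Three automated rules, each an independent boolean mask so that
application order cannot matter, plus a user-supplied manual interval
list (the visual-inspection step of the original protocol cannot be
automated):

* confidence == 3 required (the tracker's 0–3 quality metric);
* ‖v‖ ≤ 3.05 m/s (momentary tracking-loss velocity spikes; the threshold
  is an average jogging speed);
* calibration segments excised;
* retained frames classed low if ‖v‖ < 0.75 m/s, else high.

Tie conventions, fixed because the verbal rules use strict
"above"/"below": exactly 3.05 m/s is retained; exactly 0.75 m/s is high.
The velocity norm is frame-invariant, so it is computed before alignment
without consequence.  When one frame violates several rules the reported
reason follows the precedence calibration → confidence → speed → manual.

## Orientation statistics

Moments use the population (non-bias-corrected, Fisher) definitions of
skewness and excess kurtosis — the default behaviour of
`scipy.stats.describe` — and SD with denominator n−1.  At the sample
sizes involved (10⁵–10⁶) the bias corrections are far below sampling
error.

**Asymmetry.**  The pitch distribution's asymmetry is quantified as the
ratio of one-sided RMS deviations of the samples strictly below/above the
distribution peak, reported as larger/smaller with an explicit flag for
which side is heavier (below the mode = forward/downward pitch).  The
peak is the argmax of a Gaussian KDE whose bandwidth is 3× Scott's rule:
with a plain Scott bandwidth the mode estimate wanders by about a degree
between realizations and dominates the ratio's variance (sensitivity
≈ 0.055 per degree of mode error), while the pilot oversmoothing pins it
down at the cost of a small deterministic shift that the synthetic
calibration accounts for.  The scale is a parameter.  A multimodal KDE is
flagged and logged, not rejected.  RMS was chosen as the dispersion
measure because it is the natural second-moment analogue of "variability"
about a point.

**KDE priors.**  Plain Gaussian kernel sums evaluated exactly (chunked)
on a 1°-spaced grid, bandwidth by Scott's rule, renormalized to integrate
to one over the stated range (±90° pitch, ±120° roll — the ranges over
which the psychophysical comparisons are defined).  Samples outside the
range are clipped out with a logged count.  The KDE is hand-rolled
(≈10 lines) rather than `scipy.stats.gaussian_kde` because the
range-renormalization semantics and an exact kernel-sum contract are part
of the module's interface; the unit tests cross-check it against scipy.
Statistics are linear, not circular: upside-down orientations do not
occur, so the distributions are not wrapped.

## Gravitoinertial spectra

`a_grav(t) = R(q(t)) · g_world` and `a_inert = a_total − a_grav`, which
makes additivity exact and ‖a_grav‖ constant at 9.81 m/s² by
construction.  PSDs are Welch estimates at fs = 62.5 Hz, nfft = 512
(0.122 Hz bins), Hann window, 50% overlap, per-segment mean removal.
Gaps from the exclusion mask are handled by estimating each contiguous
retained run separately and averaging with weights equal to each run's
number of windowed sub-segments — never by concatenation, which would
fabricate discontinuity power.  Runs shorter than nfft are skipped and
counted.

The crossing point per axis is detected on log₁₀ spectra smoothed with a
3-bin moving average (DC excluded): the lowest frequency where
log P_inert − log P_grav changes sign from negative to positive and stays
positive for ≥ 3 bins, refined by linear interpolation of the log-power
difference.  The persistence rule makes "the" crossing well-defined on
noisy spectra; "no crossing" is a valid result, not an error.  P_total is
not asserted to equal P_grav + P_inert (the components are correlated);
each PSD is instead Parseval-consistent with its own time series.

## Bayesian tilt-perception model

Priors are the empirical KDEs on the whole-degree grid.  The likelihood
at true tilt θ is a Gaussian centred on θ with eccentricity-dependent SD

    linear:  σ(θ) = a₀ + σ·|θ|
    shear:   σ(θ) = a₀ + σ·s·|sin θ|

The shear form follows the gravity component tangential to the utricular
macula.  The shear scale defaults to s = 90°, which makes the two laws
agree at 90° eccentricity for equal σ, so fitted σ values are comparable
across kinds.  The additive floor a₀ defaults to 2.3° but is a
configuration value with no empirical authority — every fit report echoes
the value actually used.  The posterior is the normalized pointwise
product on the grid and its mean is the percept; bias = posterior mean −
true angle, so negative bias at positive tilts is attraction toward
upright.  Because the grid truncates the likelihood, a flat prior yields
exactly zero bias only for angles a few likelihood-SDs away from the grid
edge; near the edge a small inward pull is inherent to the grid
formulation.

σ is fitted by minimizing RSE = √(Σ(yᵢ−ŷᵢ)²/(n−2)) over observed angles
(whole-degree lookup, no interpolation): a deterministic coarse scan
(200 log-spaced values plus zero and the bounds) followed by bounded
scalar refinement (xatol 1e−12) around the scan minimum.

## Synthetic generator

The generator produces 6-DOF odometry with the statistical structure the
analysis assumes.  Design:

* **Activity**: a two-state (stationary/locomoting) Markov chain at 1 Hz,
  stationary occupancy 0.9225, mean dwells ≈ 71 s / 6 s.  A one-pole
  0.4 s envelope turns the state into a smooth speed target (1.3 m/s
  walking, slow OU modulation, 8% step-frequency speed oscillation, a
  slowly wandering heading).
* **Orientation**: per-angle Ornstein–Uhlenbeck processes (relaxation
  0.75 s, a free parameter — the study conditions do not pin down
  orientation autocorrelation) pushed through split-normal-mixture
  marginals via a Gaussian copula, so the stationary marginal is exact.
  The Gaussian process is additionally smoothed by an exactly
  renormalized 0.1 s one-pole filter: a raw AR(1) recursion implies
  divergent sample-level angular velocity, which is both unphysical and
  leaks into the velocity channel through the neck lever (below).
  Marginals are truncated at ±89° (pitch) / ±120° (roll) so sampled
  angles cannot cross the Euler gimbal point.
* **Pitch marginal**: a split normal (forward side 1.477× wider than
  backward) plus a 12%-weight copy scaled 2.23× for moderate excess
  kurtosis; during locomotion the marginal shifts 6° downward, narrows
  slightly (×0.9) and becomes more asymmetric (×1.15), reproducing the
  qualitative low/high-velocity KDE contrast.  **Roll marginal**: a
  Gaussian core (SD 4.98°) with a 5%-weight heavy tail (SD 17.3°), which
  gives excess kurtosis ≈ 7.26 analytically.  The numeric defaults were
  derived once (`scripts/calibrate_generator_defaults.py`) by solving the analytic
  pooled densities against the target pooled statistics — pitch mean
  −1.7701°, SD 16.8167°, excess kurtosis 1.7467, one-sided RMS ratio 1.38
  under the package's own mode estimator; roll SD 6.2108°, excess
  kurtosis 7.2592 — and then frozen.
* **Kinematics**: the head pivots about a neck point 0.12 m below it, so
  orientation motion produces real translation.  This term is what sets
  the nasal-occipital (X) crossing point: equating the lever-arm
  acceleration with the first-order gravitational pitch signal gives
  (2πf)² ≈ g/L, i.e. ≈ 1.4 Hz, independent of the orientation spectrum —
  hence X crossings above the Y/Z ones, matching the observed ordering.
  Locomotion adds a 2 m/s² vertical sinusoid at the 2 Hz step frequency.
* **Residual inertial jitter**: OU acceleration noise (corner ≈ 2 Hz)
  with SD 0.78 m/s² stationary / 2.0 m/s² locomoting / 0.1 m/s² during
  calibration stillness.  The stationary level stands in for the real
  small translations of "low-velocity" natural behaviour (postural sway,
  fidgeting) and is what places the Y/Z crossing points near 0.7 Hz; it
  is deliberately larger than pure sensor noise.
* **Conservation**: `a_total = R(q)·g_world + a_inert` is assembled from
  the stored quaternion through the same code path the decomposition
  uses, so the gravitational/inertial round trip is exact to float
  round-off.
* **Artifacts**: Poisson-timed confidence drops (0.2–2 s, confidence
  0–2, 6/h) and velocity spikes (1–5 samples, magnitude in (3.05, 8]
  m/s, 4/h), restricted to plain data segments so filter accounting is
  exact.
* **Determinism**: one seeded generator drives everything in fixed
  order; identical configurations are bit-identical.

What it does **not** emulate: the near-zero *standardized* pitch
skewness that real data shows alongside its peak asymmetry (a
split-normal mixture with a 1.38 one-sided ratio necessarily has a
nonzero third moment, ≈ −0.45 here; matching both would require
compensating opposite-side tails), visual scene content, activity
semantics
(the two states are not "sitting" vs "walking", just occupancy classes),
slow sensor drift or genuinely non-stationary behaviour across hours,
inter-individual variability, and any coupling between orientation and
translation beyond the neck lever.  Passing tests therefore show that the
pipeline's estimators are correct and well-calibrated on data with the
documented structure — not that real recordings have that structure.

## Problem sizes and statistical power

The end-to-end checks run a six-hour recording (1.35 M samples,
~40 s to generate and analyse).  At this size the sampling SDs of the
targeted quantities — low-velocity fraction 0.7 pp, asymmetry ratio
0.020, Z-crossing 0.019 Hz, measured across eight calibration seeds —
are at least 2.5× smaller than the documented target bands, so a failure
indicates a real defect rather than an unlucky seed.  Monte-Carlo checks
use 100 draws (alignment recovery, σ recovery).  The σ-recovery
benchmark uses 13 angles (−90°…90° in 15° steps) with 0.5° observation
noise.

## Known limitations

* The asymmetry ratio depends on the mode-estimation bandwidth; the
  pilot-oversmoothing choice is documented and exposed, but a different
  choice shifts the ratio by a few hundredths.
* The additive likelihood floor (2.3°) and the units of σ are
  conventions; fitted σ values are only comparable within those
  conventions.
* Grid-truncation bias in the Bayesian model grows near the prior range
  edges (see above).
* Re-calibration blocks inherit the anatomical pitch offset from the
  last static segment; true anatomical slippage between static segments
  is not distinguishable from sensor slippage.
* The crossing detector's 3-bin smoothing and persistence rule are part
  of the definition of "crossing point"; raw-spectrum crossings can
  differ on noisy data.
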