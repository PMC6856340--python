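# Methods

This note documents the models behind `swaymetrics`, the parameter choices
that matter, and what the synthetic data can and cannot establish.

## Signal model and preprocessing

A trial is a planar COP trajectory (anterior-posterior and medio-lateral
displacement, mm) on a uniform time base.  Raw acquisitions at 1 kHz are
low-pass filtered with a zero-phase 4th-order Butterworth at 10 Hz,
resampled to 100 Hz, and mean-removed per channel.  Postural sway power is
concentrated below a few Hz, so 10 Hz retains the physiological band while
suppressing sensor noise.  The analysis rate must be pinned because the
Markov-chain transition statistics and λ₂ depend on the sampling lag; both
the cutoff and the target rate are configurable.  Preprocessing is
idempotent: a trial already at the target rate is only re-centred, which
changes nothing.

Three directional series are derived: the zero-mean AP and ML channels,
and the radial series — the per-sample Euclidean distance from the mean COP
point, which is invariant to rotation of the force-plate axes.

## Invariant density analysis

The state variable is the distance of the COP from its centroid: |x| for
the signed AP/ML series, the radial distance itself for Rad.  Distances are
binned into `n_states = 60` uniform half-open bins spanning [0, pooled
maximum], with the last bin closed.  The bin geometry is pooled across all
trials entering a comparison: entropies computed on different state spaces
are not comparable.  Distance (rather than signed displacement) is used
because D̄ and D95 are defined through the cumulative probability of
containing the COP, and because the second-eigenvector boundary z_λ2 is
interpreted as a radius separating an inner, freely-diffusing region from
an outer, actively-controlled one.

Transitions are counted at lag 1 sample (10 ms at the analysis rate) and
every cell receives an additive pseudomass ε = 10⁻⁸ before row
normalization, making the chain irreducible and aperiodic so the invariant
density exists and is unique.  One subtlety matters in practice: a state
visited only during the trial's final dwell has no observed exit — the
dwell is right-censored.  Left uncorrected, its row would be a near-pure
self-transition and the tiny regularization would make it almost absorbing,
collapsing the invariant density onto a state that the trajectory visited
once.  Such censored self-transitions are therefore zeroed before
regularization, which turns the state into a uniformly-escaping one with
negligible stationary mass.  (Only the terminal dwell can produce such a
row: any interior visit necessarily records an exit.)

π is computed from the eigen-decomposition of Pᵀ (eigenvalue nearest 1)
and cross-checked against power iteration to 10⁻⁸; disagreement raises an
error rather than returning silently.  Entropy uses base-2 logarithms with
0·log 0 ≡ 0, so 0 ≤ H ≤ log₂ 60 ≈ 5.91 bits.

λ₂ is the second-largest eigenvalue by modulus (ties broken by larger real
part).  Empirical sway chains occasionally yield a complex λ₂; its modulus
is reported and a warning emitted.  z_λ2 uses the *left* eigenvector of λ₂:
left eigenvectors for eigenvalues ≠ 1 are exactly orthogonal to the
all-ones vector, so their components sum to zero and a sign change must
exist whenever the eigenvector is not degenerate.  The sign is fixed so the
first appreciable component is positive, and the first sign change
(scanning outward from the centroid) is linearly interpolated between bin
centres.  An eigenvector with no sign change returns NaN with a warning.

## Stabilogram diffusion analysis

The mean-square displacement msd(Δt) = ⟨[x(t+Δt) − x(t)]²⟩ is averaged over
all overlapping pairs, for lags up to 10 s (one third of a 30 s record —
longer lags have too few independent pairs).  The radial curve uses planar
increments Δap² + Δml², i.e. the resultant planar diffusion plot; its
diffusion coefficients are still defined as one-half of the fitted slope,
the same convention as the scalar directions.

The critical point is the first minimum of the second derivative of the
linear msd curve.  An empirical msd is noisy, so the curve is first
smoothed by a local quadratic (Savitzky–Golay) fit over a 0.5 s window and
the second derivative taken by central differences; the search is
restricted to lags 0.2–5 s.  A minimum must also be appreciably concave
(second derivative below −10⁻⁸·max|msd|/δ², with δ the lag step) so that
float-level jitter on a straight line can never fabricate a critical point;
a curve with no qualifying dip returns a NaN sentinel recorded in the
result diagnostics.

Short-term fits use lags from the first lag to 0.9·Δt_c, long-term fits
1.5·Δt_c to 10 s; the margins keep both regressions clear of the regime
transition and are configurable.  D = slope/2 on the linear axes; H =
slope/2 on log-log axes (msd ~ Δt^2H), so a ballistic ramp gives H = 1, a
random walk H = 0.5, and a saturating bounded process H → 0.

## Feedback control law

ω_c = K_p θ_p + K_i ∫θ_p dt + K_d θ̇_p, clipped to ±25 rad/s (≈ 4 Hz of
contactor rotation, above which the stimulus would blur and could become
uncomfortable).  The practical configuration is derivative-only
(K_p = K_i = 0, K_d = 1 by default; the gain is exposed because tuned
values are subject-dependent).  The pitch rate is a backward difference at
the sample rate.  Derivative-only feedback makes the output invariant to
any constant offset in the pitch signal, which is what makes the device
robust to IMU drift, and means a subject holding a constant lean feels
nothing.

## Synthetic data

**Pendulum simulator.**  Sway is a linearized single-link inverted pendulum
(point mass m = 70 kg at h = 1 m): I θ̈ = mgh·θ − T(t), with ankle torque
T = K θ̂(t−τ) + B θ̇̂(t−τ) produced by a delayed (τ = 150 ms) PD "neural"
controller acting on noisy state estimates.  K = 1.1·mgh (stabilizable by
construction), B = 350 Nms/rad.  The COP is the ankle torque divided by
body weight, in mm; each trial is integrated by Euler–Maruyama at 1 ms
steps for 30 s.

Noise enters in two places: white motor torque noise (1 Nm·s^-1/2) and
coloured sensory estimation noise (Ornstein–Uhlenbeck, 0.1 s correlation
time) added to the delayed states used by the controller — 0.005 rad/s
stationary sd on the rate estimate, with the angle-estimate noise scaled
from it by a 0.1 s equivalence time.  These magnitudes were chosen once so
that the preprocessed COP sd falls in the physiological few-mm range
(≈ 7–9 mm under the baseline condition, appropriate for eyes-closed,
head-extended standing) and are frozen as defaults.

Sensory augmentation is modelled *only* as a change in estimate quality:
`snr_gain` multiplies the AP sensory noise (0.5 for the augmented
condition, 1.0 for baseline).  The ML axis is an independent, identically
structured process always at gain 1, because the device encodes AP sway
only.  Nothing else differs between conditions, so any downstream effect
is attributable to the sensory mechanism — reduced estimation noise
tightens the closed-loop sway distribution, which lowers its entropy.

**Two-regime surrogate.**  For validating SDA independently of the
pendulum: position x relaxes toward zero at rate 0.5 s⁻¹ while integrating
an OU drive with 0.2 s correlation time (drive intensity 1 mm·s^-1/2).
Over lags short relative to the drive correlation time the motion is
near-ballistic (persistent, Hs ≈ 0.9); past the mean-reversion time the
variance saturates (antipersistent, Hl ≈ 0.2), with the regime change
around 0.2–0.3 s — the canonical two-regime stabilogram shape.

**Cohort builder.**  15 subjects × 2 conditions × 10 trials.  Each subject
receives one multiplicative log-normal jitter (sd 0.1) of the stiffness
margin, damping and noise intensities, used for both conditions; every
trial gets an independent seed spawned deterministically from a single
master seed, so a cohort is bit-reproducible.

**What the synthetic data do not show.**  The simulator reproduces the
statistical signatures the analyses assume (bounded correlated sway,
two diffusion regimes, entropy responsive to sensory noise) but is not a
biomechanical model of any individual: it has one segment, one feedback
pathway, stationary parameters, and Gaussian noise.  Passing tests on it
demonstrates that the pipeline measures what it claims to measure and that
an SNR-only manipulation produces the expected directional effects; it
does not validate physiological parameter values, and absolute measure
values (e.g. H in bits) depend on the binning convention and cohort
pooling and are comparable only within an analysis.

## Statistics

Trials are averaged within subject and condition; each measure in each
direction is compared with a two-tailed paired t-test (df = n−1) on the
ON − OFF subject means, with Cohen's d for paired samples
(d = |mean diff|/sd diff = |t|/√n).  p < 0.05 is flagged significant and
0.05 ≤ p < 0.10 a tendency; no multiple-testing correction is applied —
flags are descriptive, mirroring how such tables are conventionally
reported.  A measure whose paired differences are identical and nonzero
(possible for quantities quantized to a coarse grid, such as the critical
lag) has no defined t and is reported as undetermined rather than
failing the whole table.  The η² → f conversion f = √(η²/(1−η²)) is
provided for a-priori power calculations.

## Numerical choices and degenerate inputs

- Bin edges are half-open with the last bin closed; a value exactly on an
  interior edge belongs to the upper bin; values beyond the last edge are
  clipped into the last bin with a warning.
- Fewer than 2 states, an all-zero pool, an empty state sequence, or a
  sequence no longer than the lag are rejected.
- A constant series yields zero msd everywhere; fits on such regions return
  D = 0 and the log-log fit is refused (undefined).
- Trials shorter than twice the filter settle time (0.6 s at the default
  cutoff) are rejected rather than filtered with dominant edge artefacts.
- The pendulum integrator raises an instability error naming the offending
  parameters if |θ| exceeds 0.5 rad, rather than returning a diverged
  trajectory.

## Problem sizes

Default analyses use 30 s trials at a 100 Hz analysis rate (3,000 samples),
60 states, 1,000 msd lags, and the full 15 × 2 × 10 cohort (300 trials);
the end-to-end cohort pipeline (simulate, analyze, compare) completes in
about two minutes on a single CPU.
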