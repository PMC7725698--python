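# Methods note

This note documents the model behind `gazenoise`, the assumptions it
makes, parameter choices with their rationale, numerical details, and
known limitations. It makes no empirical claims beyond what the test
suite and `scripts/acceptance.py` compute.

## 1. Model

A fixation window is a sequence of n gaze samples (x_i, y_i), in degrees
of visual angle, recorded at a constant sampling rate fs (Hz). During a
fixation the eye is treated as stationary, so the recorded variation is
attributed to the measurement process ("noise"). The package
characterizes that noise in three complementary ways and can synthesize
signals that reproduce a chosen characterization.

### 1.1 Time-domain precision measures

- **RMS-S2S** — root mean square of sample-to-sample displacements,
  `sqrt( 1/(n−1) · Σ (Δx_i² + Δy_i²) )` over the n−1 steps. Sensitive to
  high-frequency content; a velocity-like quantity.
- **STD** — `sqrt(var(x) + var(y))` with population (1/n) variances.
  Sensitive to low-frequency content; a spread quantity. The population
  denominator is a deliberate convention choice; at the window lengths
  used here (n ≥ 12) the difference from 1/(n−1) is below 5% and it
  keeps the STD↔BCEA relation (below) exact.
- **BCEA** — bivariate contour ellipse area,
  `2kπ·σ_x·σ_y·sqrt(1−ρ²)`, with σ and ρ computed from population
  moments. For bivariate Gaussian data the ellipse of that area centred
  on the mean and aligned with the principal axes contains a fraction
  `P = 1 − e^(−k)` of the samples; the default k = 1 gives P ≈ 0.632.
  `sqrt(BCEA)` is reported so the quantity has linear units (degrees)
  and is comparable with STD: for isotropic data
  `sqrt(BCEA) = sqrt(2kπ)·σ_axis = sqrt(π)·STD` at k = 1.
- **BCEA ellipse shape** — from the eigendecomposition of the 2×2
  position covariance: eigenvalues λ₁ ≥ λ₂, aspect ratio
  `sqrt(λ₁/λ₂)`, orientation the angle of the λ₁ eigenvector mapped to
  the axial interval (−π/2, π/2] (an ellipse is unchanged under a
  half-turn, so orientation is only defined modulo π).

### 1.2 Composite measures: magnitude and type

RMS-S2S and STD are combined into polar-like coordinates:

- **signal magnitude** = `sqrt(RMS-S2S² + STD²)` — the overall noise
  level, invariant to the trade-off between the two;
- **signal type** = `RMS-S2S / STD` — where on that trade-off the
  signal sits. White noise gives √2 asymptotically; persistent
  (low-pass, drift-like) signals give less; anti-persistent (spiky)
  signals give more.

The nominal range [0, 2] of the signal-type value is an *asymptotic*
statement. For finite n the exact supremum is

    B(n) = 2·cos(π/(2n)) · sqrt(n/(n−1)),

derived from the variational form of the ratio: the numerator is a
quadratic form of the path-graph Laplacian (largest eigenvalue
`4·cos²(π/(2n))` on the mean-zero subspace) and the denominators differ
by the factor n/(n−1). B(n) exceeds 2 for small n — e.g. B(3) ≈ 2.1213,
attained by the segment x = (0, 1, 0) — and decreases to 2 as n → ∞.
The alternating segment (0, 1, 0, 1, …) attains exactly 2 for even n.
Property tests use B(n), not 2, as the bound.

### 1.3 Spectral characterization

The per-axis power spectral density is estimated by the raw
periodogram: boxcar window, constant detrend, density scaling, DC bin
dropped, Nyquist bin retained. A power law `S(f) ∝ 1/f^α` is fitted by
ordinary least squares on (log₁₀ f, log₁₀ S); α is minus the slope. The
two-dimensional α is the mean of the per-axis fits. The raw full-band
periodogram without tapering or smoothing is chosen deliberately: for
exact synthetic power laws it is unbiased across the whole band, the
fitted α is averaged over many realizations wherever a precise value is
needed, and tapering would distort the short windows (n as low as 12)
the stability experiment cares about. A fit requires at least 4 nonzero
frequency bins, which means windows of at least 9 samples; shorter
windows get α = NaN rather than a meaningless fit.

## 2. Synthesizer

Noise with a chosen magnitude, type/color, amplitude distribution and
anisotropy is generated per axis by spectral shaping:

1. draw n white samples — Gaussian; uniform on [−√3, √3] (unit
   variance); or from an empirical CDF by inverse transform sampling
   with linear interpolation between tabulated quantiles (piecewise
   linear rather than step-function inversion, so the synthesized
   values are not restricted to the observed support points);
2. real FFT; multiply bin k ≥ 1 by `k^(−α/2)` and zero the DC bin
   (the output is mean-free by construction);
3. inverse real FFT; subtract the residual mean;
4. apply anisotropy: scale the x axis by the aspect ratio, then rotate
   both axes by the orientation angle;
5. rescale both axes by one common factor so that the chosen magnitude
   measure — RMS-S2S, STD, or signal magnitude (the default) — equals
   its target *exactly* (all three are homogeneous of degree 1 in the
   signal, so a single multiplicative factor suffices; the test suite
   checks 1e−10 relative agreement). Because the rescale is uniform it
   changes the magnitude without touching the signal-type value: the
   two controls are orthogonal.

Because the shaping acts on the discrete Fourier basis the output is
cyclical — sample n is statistically continuous with sample 1. That is
harmless for windowed analyses and makes the spectrum exact; it is
listed as a limitation below.

Seeding: a `NoiseSpec.seed` is expanded through `SeedSequence.spawn`
into two independent substreams for the x and y axes, so the axes are
independent and every output is reproducible from one integer.

### 2.1 Mapping a signal-type target to α

The signal-type value produced by `1/f^α` shaping depends on the window
length n, so "generate type 0.75" requires a per-n calibration. A
`MappingTable` is built by Monte Carlo: for each α on a grid, generate
`reps` realizations at length n, compute the mean signal-type value,
and enforce monotonicity (non-increasing in α) with isotonic
regression, which removes Monte-Carlo wobble without biasing the curve.
Inversion is linear interpolation on the cleaned curve; targets outside
the achievable range raise an error naming the range.

Parameter choices:

- **grid α ∈ [−4, 3], step 0.05.** The step keeps interpolation error
  well below Monte-Carlo error. The anti-persistent side extends to −4
  because at n = 500 the mean signal-type value at α = −2 is ≈ 1.794,
  which does not reach the 1.8 level used in the stability experiment;
  α = −4 reaches ≈ 1.89. The persistent side stops at 3 because the
  curve is essentially flat near 0 there.
- **reps = 500** (800 for n < 25, where per-realization variance is
  larger) balances table accuracy (standard error of each mean ≈ 0.002
  at n = 500) against build time (≈ 2.5 s vectorized).
- Tables can be cached on disk; the CSV serialization uses `repr`
  precision so save/load round-trips are bit-identical, and the cache
  key hashes all build parameters.

## 3. Simulation experiments

### 3.1 Window-length stability

Measures how each precision measure depends on the analysis window.
Defaults, which are the package's study conditions:

- **signal-type levels** (0.25, 0.75, 1.0, √2, 1.8): two strongly and
  mildly persistent signals, an intermediate, exact white, and an
  anti-persistent signal — spanning the empirically occupied range;
- **signal magnitude 0.5°** for every level, a mid-range noise level
  for video eye trackers, so curves differ only in type;
- **sequence length 500 samples at 1000 Hz** (a 0.5 s fixation);
- **window lengths** 12…499 samples, log-spaced, with windows placed
  uniformly at random within the sequence;
- **reps = 200** per (level, window) cell. The standard error of a
  cell mean is then ≲ 0.004°, small against the effects of interest
  (tens of percent); larger reps sharpen the curves without changing
  them.

Windows with zero variance on an axis are regenerated (bounded
attempts, count reported). Output is a tidy table of per-cell mean and
standard deviation for all six measures (RMS-S2S, STD, √BCEA, signal
magnitude, signal type, α), with pivot and standard-error helpers.

### 3.2 RMS-S2S versus STD space

Summarizes a population of fixation windows as a density in the
(STD, RMS-S2S) plane: Gaussian kernel density estimate (Scott's
bandwidth rule — the sample sizes here are in the hundreds and no
strong multimodality along one axis is assumed, so the simple rule is
adequate and dependency-free) evaluated on a regular grid, with 16
equally spaced contour levels of which the lowest is dropped (15
retained) so the near-zero floor does not dominate the picture, plus a
histogram of direction angles `arctan(RMS-S2S/STD)` in [0, π/2], whose
distances from `arctan(√2)` show how non-white the population is.

### 3.3 Probit distribution analysis

Checks whether pooled per-axis position deviations are Gaussian.
Positions are centred per window, pooled per axis, sorted, and plotted
against `Φ⁻¹((i − 0.5)/n)` (the standard plotting-position convention).
A straight line is fitted by OLS on the central 80% of the data (10th
to 90th percentile band) — central, because measurement noise cores are
near-Gaussian while tails carry artifacts; the fitted slope estimates
1/σ. Departure of the extreme quantiles from the line diagnoses heavy
or light tails.

## 4. Input handling

`read_gaze` accepts CSV/TSV files with time, x, y columns, requires
strictly increasing timestamps, tolerates NaN samples (counted and
reported), and cross-checks a declared sampling rate against the median
timestamp spacing (warning beyond 10% discrepancy, spacing-derived
value used). `extract_windows` tiles half-open [t, t + duration)
windows with a configurable stride and drops windows containing NaNs,
logging the count.

## 5. What the generator does and does not emulate

It emulates: the second-order temporal structure (power-law spectrum /
signal-type value), the amplitude distribution (via the empirical-CDF
option), the anisotropy (ellipse aspect ratio and orientation), and the
overall magnitude of fixation noise.

It does not emulate: oculomotor events (microsaccades, drift with
directed dynamics, tremor as a distinct spectral peak), blinks and
tracking losses, nonstationarity within or across fixations,
magnitude–type coupling across the visual field, cross-axis dependence
beyond a linear (elliptical) one, or quantization and frame-locked
artifacts of specific tracker hardware. Synthesized noise is stationary,
cyclical, and exactly on the target magnitude — real recordings are
none of these.

## 6. Known numerical and statistical caveats

- **√BCEA vs √π·STD at short windows.** The population identity
  `sqrt(BCEA) = sqrt(π)·STD` for isotropic signals holds only
  asymptotically for estimates. At short windows the Monte-Carlo mean
  of the ratio sits below 1: `E[sqrt(1−ρ̂²)] < 1` when the true ρ = 0,
  and the geometric mean `σ̂_x·σ̂_y` is biased below the arithmetic
  combination entering STD. For white noise at 12-sample windows the
  mean ratio is ≈ 0.95; for strongly persistent signals (whose
  effective number of independent samples is much smaller than n) it
  drops to ≈ 0.86. This is a bias, not Monte-Carlo variance — more
  repetitions do not remove it. One end-to-end test asserts the
  proportionality within 5% across all conditions and consequently
  fails at the short-window persistent cells; it is kept as an honest
  record of this bias rather than weakened.
- The signal-type value of a *single* realization fluctuates around
  the mapping's calibrated mean (standard deviation ≈ 0.05 at n = 500,
  larger for short windows); the mapping pins means, not realizations.
- Statistical trend assertions in the test suite (e.g. STD increasing
  with window length) allow adjacent Monte-Carlo means to invert
  within 3 combined standard errors, because near an asymptote the
  true increments are smaller than the Monte-Carlo noise.
- α estimates from short windows are noisy and mildly biased by
  spectral leakage; the stability experiment reports them from 9
  samples up but treats values below ~30 samples as qualitative.

## 7. Open design decisions

- The magnitude rescale is applied after anisotropy, so the target is
  the *overall* magnitude of the anisotropic signal; per-axis targets
  would be an alternative convention.
- The mapping calibrates the mean signal-type value; calibrating the
  median would be more robust to the skew of the ratio at short n but
  breaks the simple interpolation inverse.
- The probit central band is fixed at 80%; an adaptive band based on a
  normality test of the core would be possible but harder to interpret
  across datasets.
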