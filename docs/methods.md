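# Methods

`gaitagree` validates a sparse (~12.5 Hz) wearable accelerometer against a
dense (60 Hz) criterion recording of the same walking bout. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic data can and cannot show.

## Signal model and conventions

All accelerations are specific force in units of g, in each sensor's local
frame. A static vertical axis therefore reads about −1 g; the simulated
vertical (x) channel carries a gravity baseline of −1.0 g, the
anteroposterior (y) and mediolateral (z) channels a baseline of 0.

Differences in every agreement statistic are **criterion minus sensor**, so
a sensor that reads high produces a negative bias.

Clock convention: each device records time stamps on its own clock, starting
at 0. `SensorModel.clock_offset` is the world time at which that clock reads
0. The synchronization lag is defined by `sparse(t + lag) ≈ criterion(t)`,
which equals `criterion_offset − sparse_offset`; the simulator's ground
truth records exactly this quantity, so recovery tests compare the two
directly. (A sensor that starts later records "advanced" content, which is
why the lag of an event, read off the two clocks, has the opposite sign —
the package standardizes on the offset-difference convention throughout.)

## Synthetic gait generator

The generator emulates thigh-worn recordings of overground walking at the
cohort cadence:

- **Waveform family**: per axis, a truncated Fourier series (4 harmonic
  pairs by default, ≤ 8 supported) at the stride frequency, plus the gravity
  baseline. A closed-form family makes every downstream recovery test exact.
- **Stride frequency**: default 110/120 Hz ≈ 0.917 Hz (cadence 110
  steps/min, two steps per stride).
- **Bout length**: 12 cycles ≈ 13 s, matching a ~15 m straight-line walk at
  a self-selected elderly pace.
- **Cycle-to-cycle variability**: each cycle's period is jittered
  (relative SD 3 %) by time-warping a shared piecewise-linear phase, so the
  waveform stays continuous at cycle boundaries; each cycle's amplitude is
  scaled (relative SD 5 %) with the scale interpolated between cycle
  midpoints, again preserving continuity. Outside the bout the phase
  extrapolates at the nominal rate.
- **Sensor model**: sampling at the device rate starting at its clock
  offset; per-axis gain and additive bias; additive Gaussian noise
  (defaults: 0.02 g sparse, 0.005 g criterion — the criterion is a
  model-smoothed output, so its noise floor is low); quantization to the
  nearest step (default 8 g/4096 ≈ 0.002 g for the ±4 g sparse device, none
  for the criterion); clipping to the full-scale range (±4 g / ±16 g).
- The highest default harmonic sits at ~3.7 Hz, inside the 4 Hz analysis
  band; more than 99 % of the sampled variance lies below 4 Hz, consistent
  with walking signals whose power is concentrated well below 10 Hz.

Study-level simulations draw each subject's cadence from the cohort
distribution (110 ± 11 steps/min, clipped to 60–180) and give the two
trials of a subject independent cycle realizations and sensor noise,
emulating a within-session retest a few minutes apart.

**What the generator does not emulate**: soft-tissue artifact, sensor
orientation drift, gait events (heel strike/toe off), turning, starts and
stops, or pathological asymmetry. Passing tests therefore demonstrate the
pipeline's correctness on quasi-periodic band-limited signals with known
ground truth — not physiological fidelity of the waveform shape, for which
no closed form exists.

## Preprocessing

- **Filtering**: 4th-order low-pass Butterworth applied forward and
  backward (`filtfilt`, odd-reflection padding of 3 × the filter length), so
  the net phase shift is zero. "4th order" is interpreted as the design
  order of each pass (net 8th-order magnitude, the dominant convention in
  gait work); `design="net"` halves the design order instead. The default
  cutoff is 4 Hz. Filtering is per axis; the magnitude channel is computed
  *after* filtering, since the two operations do not commute.
- **Residual analysis**: for each candidate cutoff, the RMS difference
  between filtered and raw signal; a straight line fitted to the
  noise-dominated limb (cutoffs in 0.25–0.75 × Nyquist by default, where the
  white-noise residual curve `σ√(1 − f/f_Nyq)` is nearly linear) is
  extrapolated to 0 Hz, and the selected cutoff is where the residual curve
  crosses that intercept (linearly interpolated between grid points).
- **Fourier reconstruction**: ordinary least squares of the harmonic basis
  on the sensor's own time stamps (handles irregular sampling; the span need
  not be an integer number of cycles). Default 6 harmonics ≈ 5.5 Hz at
  cadence 110 — above the 4 Hz cutoff, below the 6.25 Hz sparse Nyquist.
  The fundamental starts from the autocorrelation stride estimate and is
  refined by a bounded golden-section search (±5 %) on the fit residual:
  a stride period quantized to the sample grid would dephase the basis over
  a multi-cycle window and destroy the in-basis exact-recovery property.
  Both devices are reconstructed with the same method so that identical
  inputs yield identical representations.

## Alignment

- **Synchronization** uses cubic-spline interpolants of the filtered
  vertical-axis samples, *not* the harmonic reconstructions: a strictly
  periodic representation has equivalent correlation peaks at every stride,
  and only the preserved cycle-to-cycle deviations make the lag
  identifiable. Both signals are resampled on a common 120 Hz grid over a
  centered window; the normalized cross-correlation is scanned over
  ±max_lag (default 2 s) and the peak refined by parabolic interpolation
  (snapped to the grid peak when the correlation is exactly 1, where
  refinement would only amplify rounding noise). The window spans up to 10
  strides when the recording allows (falling back toward the 5 analyzed
  cycles on short recordings): rival correlation peaks one stride apart are
  separated only by accumulated cycle deviations, and more strides give a
  safer margin at realistic noise. A peak correlation below 0.5 warns but
  does not fail. The single estimated lag is applied to all four channels.
- **Stride period**: unbiased sample autocorrelation; candidate local
  maxima in lags 0.4–2.5 s (cadences ~48–300 steps/min; the refractory lag
  excludes the half-stride peak of near-symmetric gait) must exceed r = 0.3.
  Among candidates, the earliest peak within 0.05 of the maximum is chosen —
  for an exactly periodic signal the stride lag and its multiples tie near
  r = 1, and the earliest is the stride. Parabolic refinement gives
  sub-sample resolution.
- **Segmentation**: the first stride of the analysis window is the
  template; each subsequent boundary is the template-correlation maximum
  within ±25 % of the stride period around its expected position (half-open
  cycles, correlation ≥ 0.5 required). Boundaries are self-similarity
  anchors, not gait events. Placing the last boundary needs roughly one
  extra stride of data, so a bout must contain about `n_cycles + 1.3`
  strides.
- **Averaging**: each cycle's time axis is mapped linearly to 0–100 % and
  every channel evaluated on a 101-point grid; pointwise mean and SD across
  the five cycles. For the statistics the averaged cycle is re-sampled at
  60 Hz over its mean stride period on a half-open grid (65 points for a
  1.09 s stride).

## Agreement statistics

- **Non-parametric CCC**: `1 − E|X−Y|²/E|X−Y′|²` with both expectations
  estimated by U-statistics (within-pair mean; mean over all cross pairs
  i ≠ j). For bivariate data this converges to Lin's moment estimator, which
  serves as the cross-check in tests, never as the implementation. The
  default CI applies the Fisher z-transform with a jackknife variance
  (computed in O(n) from running sums); a percentile bootstrap is the
  alternative.
- **Percentile Bland–Altman**: bias = median of the differences, LoAs =
  empirical 2.5th/97.5th percentiles with numpy's linear interpolation
  between order statistics (the 2.5th percentile of ~65 points is
  interpolation-sensitive, so the definition is fixed and documented).
  CIs by percentile bootstrap, default B = 2000, seeded. At least 20 pairs
  are required for percentile LoAs; smaller feature families must be pooled
  first.
- **DTW**: classic dynamic programming with absolute-difference local cost,
  symmetric steps {(1,0), (0,1), (1,1)}, no window, no slope weighting; ties
  in back-tracking prefer the diagonal. The distance is the raw cumulative
  cost — under that reading the NSI normalizer `M = n_samples × range`
  makes `NSI = (M − d)/M` dimensionless and scale-free.
- **ICC(A,1)**: two-way ANOVA with grid points as rows and trials as
  columns; `ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`; CI via
  the F-based interval with a Satterthwaite degrees-of-freedom
  approximation. Duplicated trials (MSE = MSC = 0) return exactly 1 with a
  degenerate CI. Test–retest ICC is computed on the shared 101-point
  percent-cycle grid, because two trials' 60 Hz discretizations can differ
  in length when stride periods differ.
- **Normality screen**: a Lilliefors-corrected Kolmogorov–Smirnov test
  (parameters estimated from the sample) is reported with each comparison;
  the pipeline's primary path is already the non-parametric CCC and
  percentile Bland–Altman.
- **Frequency domain**: periodogram of the mean-removed, 4× zero-padded
  60 Hz discretized averaged cycle, normalized so the density integrates to
  the sample variance. Peaks are local maxima with prominence ≥ 5 % of the
  global maximum, at least 0.2 Hz apart (suppressing leakage sidelobes),
  ranked by power and truncated to 5 in the 0.25–5 Hz band; criterion and
  sensor peaks are paired greedily by nearest frequency within a 0.3 Hz
  gate, unmatched peaks dropped. Fourier coefficients of the averaged cycle
  use the stated integral definitions with composite trapezoid quadrature
  on the closed percent-cycle grid (an FFT-bin reader is the exact
  alternative on band-limited cycles and the oracle in tests); the first
  ten pairs (21 coefficients with a0) per channel are compared.

## Study-level pooling

Per axis, all subjects' 60 Hz discretized averaged-cycle points are pooled
into one CCC/Bland–Altman computation (one value per axis). NSI, which is a
per-signal shape index, is summarized as the median across subjects with a
percentile interval. PSD-peak families are compared per axis when at least
20 matched pairs accumulate, and always in an all-axes pooled row.
Test–retest ICC is reported per device and axis, pooling subjects' grid
points.

## Numerical choices and degenerate inputs

- Resampling grids are half-open `[t0, t1)`: 1 s at 60 Hz gives exactly 60
  samples; `floor(period × rate)` points for the discretized cycle.
- Identical inputs propagate to exactly perfect statistics (CCC = NSI = 1,
  zero bias and LoA width, ICC = 1) rather than near-1 floating-point
  values; degenerate denominators (constant criterion for NSI, zero total
  variance for ICC, zero cross-pair variability for CCC) raise explicit
  errors instead of returning NaN.
- Pipeline stages surface failures with the stage name (e.g. a recording
  too short to segment names the segmentation stage and the boundary).
- Problem sizes in the test suite and acceptance script (8 simulated
  subjects, 12–16 cycles per trial, B = 150–2000 bootstrap resamples,
  20–200 Monte-Carlo seeds per check) were chosen so each check's
  Monte-Carlo error is comfortably below the asserted tolerance.

## Known limitations

- The Fourier reconstruction is a whole-trial periodic fit: it smooths away
  cycle-to-cycle variation in the sparse stream, so the sparse averaged
  cycle's SD understates true variability. Per-cycle fitting would preserve
  it at the cost of fragility at 12.5 Hz (≈ 13 samples per cycle).
- Segmentation anchors are self-similarity maxima, not heel strikes; cycle
  phase is arbitrary (consistent between devices, so agreement statistics
  are unaffected, but cycles are not anatomically registered).
- With jitter and noise both near zero the synchronization problem is
  ill-posed modulo one stride period; real gait (and the default generator)
  always carries enough cycle deviation to disambiguate.
- The 4 Hz low-pass attenuates content near the band edge (a 3.7 Hz
  harmonic loses ~33 % amplitude after two passes); fidelity checks against
  the raw generator waveform therefore disable the filter, which has its
  own analytic-response tests.
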