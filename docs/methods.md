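# Methods

This note records the definitions, conventions and design choices behind
`hrvchaos`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Input model and quality control

The unit of analysis is an RRI recording: an ordered sequence of
beat-to-beat intervals in milliseconds, identified by participant,
condition (`rest1`, `rest2`, `standing`, `cognitive1`, `cognitive2` or a
free label) and set number.  A recording is rejected whole when 1% or more
of its intervals fall outside the physiologically plausible 200–2000 ms
range (bounds inclusive, so a beat of exactly 200 ms is in range; a
fraction of exactly 1% fails, since the rule is "1% or more").  Beats are
never edited or interpolated — a recording either enters the analysis as
measured or not at all.  Indices are computed from the leading 420-s
window: a beat belongs to the window iff its cumulative end-time is at or
below 420 000 ms (no partial beats; the window is anchored at the start of
the recording since nothing pins it elsewhere).  Shorter recordings are
analysed whole with a logged warning.

## Index definitions and conventions

**Time domain.**  SDNN and SDSD are sample standard deviations (n − 1) of
the intervals and their first differences; RMSSD is the root mean square
of the first differences.  pNN50 counts adjacent pairs whose absolute
difference exceeds 50 ms and divides by the **total number of intervals**,
not the pair count — this follows the index table of the study being
replicated and differs from the Task-Force convention by (n − 1)/n, about
0.2% at n ≈ 400.  A population-normalised SDSD is kept internally because
it satisfies two exact identities used as test oracles:
RMSSD² = SDSD_pop² + (mean successive difference)² and
SD1 = SDSD_pop/√2.

**Frequency domain.**  The tachogram (interval against beat end-time) is
cubic-spline resampled to a uniform 4-Hz grid, and the PSD of the
mean-removed signal is estimated by Welch's method (Hann window, 1024-
sample segments = 256 s, 50% overlap; a single periodogram with a logged
warning when the record is shorter than one segment).  LF is the
trapezoidal integral over [0.04, 0.15) Hz and HF over [0.15, 0.4] Hz; the
seam at 0.15 Hz belongs to HF so no power is double-counted, and power
below 0.04 Hz feeds no index.  LFnorm = 100·LF/(LF + HF) and
HFnorm = 100 − LFnorm, so the two sum to 100 exactly.  The estimator chain
is the package's own choice (the index definitions fix only the bands);
every knob is exposed in the config, so exact numerical parity with any
particular HRV software is not claimed.

**Entropies.**  ApEn(m=2, r=0.2σ) uses Chebyshev template distance with
self-matches included (Pincus); SampEn excludes self-matches and counts
ordered template pairs over the first n − m start points for both template
lengths (Richman).  σ is the sample standard deviation of the analysed
window itself, so both statistics are invariant under positive affine
transforms of the data.  A constant series returns 0 by convention
(perfect regularity); SampEn with zero match counts returns NaN with a
logged warning rather than crashing a batch.

**Higuchi fractal dimension** uses lags k = 1…10 (k_max configurable) and
the standard offset-averaged normalised curve length; the FD is the
least-squares slope of ln L(k) on ln(1/k).  A constant series returns 1.
Values outside [1, 2] are possible for exotic inputs and are logged, not
clipped.  Note that at beat-rate sampling even a pure respiratory-band
sinusoid (period ≈ 4–5 beats) reads as high FD; this matters for the
synthetic presets below.

**Poincaré descriptors.**  SD1 and SD2 are population standard deviations
of the lag-1 plot projected onto the ±45° axes, i.e. of (uₙ₊₁ ∓ uₙ)/√2.
The ratio SD1/SD2 is NaN when SD2 = 0 (constant series).

**CD and ICD.**  The partition interval is I = [μ − 2σ, μ + 2σ] of the
analysed window, split into N equal half-open cells (the last cell closed
so b belongs to it).  Consecutive pairs with either endpoint outside I are
dropped from the transition counts — the partition covers only I —
with clipping to the boundary cells available as a config alternative;
which the original analysis used is not stated anywhere, and at μ ± 2σ
the choice affects only the ~5% tail mass.  p(i) is the occupancy of the
first elements of counted pairs, so Σp(i) = 1 and Σⱼ p(j|i) = 1 hold by
construction on exactly the counted data.  CD uses N = 20; ICD uses
N = 10 with Q = 4 subcells, both in natural log so ICD is commensurate
with Lyapunov exponents in nats.  The source material labels these
parameters "M", which in the defining equations is the data length; a
420-s recording has hundreds of beats, so the values are read here as the
partition cell count N, with the full window as data.  (The literal
reading — sliding 20-point windows — can be reproduced through the config
if that was the original intent.)  q(i, j) is estimated as the fraction of
the Q subcells of A_j receiving at least one observed transition from A_i;
whenever p(i, j) > 0 at least one subcell is occupied, so q ≥ 1/Q and
ICD is always finite, with ICD ≤ CD since q ≤ 1.  When every occupied
transition lands in a single subcell, ICD = CD − ln Q exactly (a frozen
test oracle).  With Q = 4 the subcell occupancy is quantised to quarters,
which rounds q upward for partially covered subcells; on the r = 4
logistic map with N = 100 this biases ICD about +0.09 above ln 2 — within
the ±0.1 band the acceptance check uses, and inherent to the estimator at
these parameters rather than an implementation artefact.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test on per-participant
values **averaged over the five sets first**.  Zero differences are
dropped (Wilcoxon's original convention; Pratt's is not implemented —
with continuous index values exact zeros essentially never occur).  Tied
absolute differences receive average ranks.  For n ≤ 12 without ties the
two-sided p is exact: the null distribution of W⁺ is built by dynamic
programming over rank subsets and the smaller tail is doubled (capped at
1).  Otherwise the normal approximation with tie correction and a 0.5
continuity correction is used.  The standardised Z always comes from the
normal approximation and carries the sign of the mean difference, feeding
the rank effect size r = Z/√N; Cohen's d = D̄/s_D uses the sample (n − 1)
standard deviation of the paired differences.

Holm–Bonferroni correction at α = 0.01 is applied within the family of 15
indices of each pairwise comparison, matching a per-column reading of the
comparison table; the pooled 75-test family is a config option since the
choice is genuinely ambiguous.

Post-hoc power and sensitivity use the standard noncentral-t
approximation for a two-tailed matched-pairs design, at effective sample
size n′ = n·ARE with ARE = 3/π (the Wilcoxon test's asymptotic relative
efficiency under a normal parent, the convention of common power-analysis
software): df = n′ − 1, noncentrality d·√n′.  The minimal detectable d is
root-found from the power function; at n = 27, α = 0.01, power = 0.8 this
yields d ≈ 0.72 (ARE = 1 gives the plain paired-t value ≈ 0.70, a second
frozen oracle cross-checked against statsmodels).

## The synthetic cohort

No public generative model exists for the study conditions, so the
package ships an integral pulse frequency modulation (IPFM) generator:
beats are emitted where the integral of (1 + m(t))/T₀ crosses successive
integers, with

m(t) = a_lf·sin(2π·0.10·t + φ₁) + a_hf·sin(2π·0.25·t + φ₂)
       + chaos_gain·z(t) + noise(t),

z(t) a zero-centred, scaled-to-[−1, 1] logistic-map (r = 4) sequence held
constant over each beat, and beat-held Gaussian noise clipped at ±4 SD.
The budget a_lf + a_hf + chaos_gain + 4·noise_sd < 1 guarantees positive
intervals.  The sinusoidal part of the rate integral is closed-form and
each threshold crossing is root-found to 1e-6 of a beat, so the only
discretisation is the beat-holding of the irregular terms.  Recordings
are 480 s so the 420-s window always fits; baselines vary across
participants (T₀ ~ U[700, 1000] ms, ±25% amplitude jitter) and every
recording is reseeded deterministically from the master seed.

Condition presets rescale a participant's rest bundle
(a_lf = 0.04, a_hf = 0.01, chaos_gain = 0.004, noise_sd = 0.0005):

* **standing** — a_lf × 1.8, a_hf × 0.35, chaos_gain × 0.25, T₀ × 0.85:
  the orthostatic shift (stronger Mayer-wave oscillation, weaker
  respiratory and chaotic components, faster heart rate), which drives all
  six chaos/complexity indices down and LF/HF up;
* **cognitive** — chaos_gain × 5, everything else unchanged: mental load
  expressed purely as stronger deterministic chaotic modulation, which
  drives all six chaos/complexity indices up while leaving the band
  structure (and hence the conventional indices) largely untouched.

These magnitudes are calibration constants chosen so the paired chaos-
index contrast is large (d ≈ 1 or more for every index) in a
27-participant cohort — the regime the replicated comparison table
reports — and are documented as generator conveniences, not physiological
claims.  The rest baseline is deliberately LF-dominant with a weak HF
component: at beat-rate sampling a strong 0.25-Hz oscillation already
saturates the Higuchi dimension near 2, which would mask the chaotic
contrast the cognitive preset must express.  Consequently the generator
reproduces the *direction* structure of the study (chaos block ↓ on
standing, ↑ on cognitive load; rest–rest null; CIR separation around
γ = 1) but not the physiological magnitudes of real HRV spectra — passing
tests demonstrate that the pipeline recovers the structure it was pointed
at, not that real cardiac data behaves this way.  Other real-data features
the generator does not emulate: ectopic beats and measurement dropouts
(QC is exercised with hand-built fixtures instead), very-low-frequency
trends, respiratory frequency drift, and day-to-day baseline shifts
beyond fresh phases/noise per set.

## Numerical and degenerate-input choices

* Constant series: ApEn = SampEn = 0, FD = 1, SD1 = SD2 = 0 with the
  ratio NaN, CD/ICD flagged as degenerate (σ = 0 gives no partition).
  Batch runs never abort on a per-index failure; failed slots carry NaN
  plus a flag and the participant is dropped pairwise for that index only.
* Cell assignment is floor-based on (x − a)/width with x = b mapped into
  the last cell; subcell assignment reuses the same rule at width/Q.
* The logistic-map fixtures discard a 1000-step burn-in; the numeric
  Lyapunov oracle is the orbit mean of ln|r(1 − 2x)| (1e5 points), skipping
  the measure-zero event x = 0.5 exactly.
* Problem sizes in the test suite: entropy brute-force oracles run on
  series of ≤ 60 points (O(n²) loops); the logistic family check uses
  1e4-point orbits for CD/ICD and the first 1500 points for ApEn/SampEn,
  whose pairwise template matrices grow quadratically; the end-to-end
  check runs the full default 27 × 5 × 5 cohort.
* Pipeline CSV/JSON output uses 6-significant-digit formatting so repeated
  runs with the same seed and config are byte-identical.

## Known limitations

* The true subcell ratio q(i, j) of the underlying dynamics (defined via
  the map's image geometry) is unknowable from data; only the occupancy
  estimator is implemented.  Its Q-quantisation bias is described above.
* Exact parity with any specific statistics package's signed-rank
  p-values is not guaranteed — tie and zero conventions differ across
  tools; the full-enumeration oracle is the ground truth here.
* Wolf/Rosenstein/Kantz Lyapunov estimators are deliberately out of
  scope (unstable on short, low-rate series like RRI), as are ectopic-beat
  correction, Lomb–Scargle/AR spectra and detrended fluctuation analysis.
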