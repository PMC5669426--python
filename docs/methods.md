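# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `memdentropy`. It is written for users who need to know
what the numbers mean, not how the code is organized.

## Preprocessing

Recordings are channels × samples matrices with one sampling rate and
unique labels. The standard offline chain is:

1. **Band-pass** — 4th-order Butterworth, default 0.5–30 Hz, applied
   forward–backward (`sosfiltfilt`), so the effective magnitude response is
   the squared 4th-order response and no group delay is introduced. A
   zero-phase filter is the natural choice for offline snippet analysis,
   where waveform timing must be preserved.
2. **Decimation** — integer factors only. An order-8 zero-phase Butterworth
   low-pass with cutoff at 0.8× the target Nyquist precedes sample
   selection; its two-pass attenuation at the target Nyquist exceeds 90 dB,
   comfortably past the 30 dB anti-aliasing requirement.
3. **Re-referencing** — subtracts the mean of a chosen reference-channel
   set from every channel (common-mode rejection); references can be
   dropped.

All three are pure functions: the input is untouched and each output
carries an appended provenance entry. Filtering defaults to preceding
decimation; the CLI exposes the opposite order too, since the two nearly
commute for in-band content (steady-state difference < 0.1% away from
edges; the 0.5 Hz high-pass edge has multi-second transients that differ
between orderings).

CSV input uses a label header row and an explicitly supplied rate; EDF/BDF
are read through `mne`. Containers mixing sampling rates across channels
are rejected.

## EMD and MEMD

Univariate EMD sifts out intrinsic mode functions by repeatedly
subtracting the mean of the upper and lower cubic-spline envelopes through
the signal's extrema. Boundaries are handled by mirroring two extrema past
each end. Sifting of one mode stops when the two-threshold
envelope-symmetry criterion holds (|mean|/amplitude below θ₁ = 0.05 on at
least 95% of samples and below θ₂ = 0.5 everywhere) *and* the candidate
satisfies the defining IMF count property (numbers of extrema and zero
crossings equal or differing by one), with a hard cap of 1000 sifting
iterations. Without the count condition, white-noise modes occasionally
retain two or three riding waves; with it, the property holds for every
mode in practice. Decomposition terminates when the residual is monotone
or has fewer than three extrema; constant or monotone inputs yield zero
modes with the input as residual.

The multivariate extension projects the d-channel vector signal onto
direction vectors on the unit (d−1)-sphere: per direction, the signal is
interpolated at the maxima and at the minima of the scalar projection, and
the direction-averaged midline of those envelopes is the common local mean
subtracted from all channels. Because every channel is sifted against one
shared mean, scales align across channels (the mode-alignment property
relied on by all cross-channel analyses). Direction sets: ±1 for d = 1
(recovering classic EMD), a seeded uniform fan on the circle for d = 2,
and a scrambled Halton sequence mapped through the normal quantile and
normalized for d ≥ 3. The default count is `max(8, 2^⌈log2(2d)⌉)`.

**Sift cap for MEMD.** The multivariate default stop is θ₁ = 0.075,
θ₂ = 0.75, α = 0.075 with **max_sift = 10**. This low cap is deliberate:
over-sifting fragments modes and destroys the quasi-dyadic filterbank
behaviour of EMD on broadband signals — empirically the zero-crossing
spacing ratio between successive modes drops from ~1.9 to ~1.45 when the
criterion is allowed hundreds of iterations, inflating the mode count for
a length-M recording well beyond log₂ M. A small fixed sifting number is
the long-established remedy. With these defaults, 2-channel white noise of
30000–52000 samples yields 16–17 modes (occasionally 18), consistent with
the 15–17 range expected for recordings of that length; the dyadic
relation `peak frequency of mode i ≈ rate / 2^(i+1)` then maps the first
six modes at 128 Hz onto 1–32 Hz.

Cumulative modes are exact running sums; by construction the last CIMF
plus the residual reproduces the input to machine precision.

## Entropy estimators

All estimators operate on snippets: short non-overlapping windows (default
100 ms, i.e. 12 samples at 128 Hz) cut from a per-channel z-scored track.
Normalization and bandwidths derive from the *windowed track*, not from
individual snippets, so all snippets of one track share one scale.

* **Rényi quadratic (RQE, bits).** `H₂ = −log₂ IP₂` with
  `IP₂ = (1/n²) Σᵢⱼ k((xᵢ−xⱼ)/σ)`, k the standard normal density. This
  pair-sum form is the package default (`as_printed`). Note it is the
  kernel mean, not a density integral: for users wanting the true plug-in
  estimate of `∫p²` the `plugin_exact` convention rescales by
  `1/(σ√2·√(2π))` with convolved bandwidth `σ√2`; both conventions differ
  only by an additive constant for fixed n and σ, so discriminability
  analyses are unaffected. Large-sample behaviour of both is verified in
  the tests against the closed form for Gaussian data.
* **Kernel Shannon (bits).** Resubstitution estimate
  `−(1/n) Σᵢ log₂ p̂(xᵢ)` with the Parzen density
  `p̂(x) = (1/(nσ)) Σⱼ k((x−xⱼ)/σ)`.
* **Sample entropy (nats).** `−ln(A/B)` where B is the match fraction of
  composite delay vectors at embedding m and A at m+1 (each channel
  extended in turn, the standard multivariate construction), Chebyshev
  distance, self-matches excluded. Defaults m = 2, τ = 1 per channel,
  tolerance r = 0.15 × SD of the z-scored track. When no matches exist the
  estimator raises a dedicated error rather than returning a number;
  curve code records such snippets as missing.

Bandwidths follow Silverman's rule `σ = σ_X (4/(n(2d+1)))^{1/(d+4)}`; for
a z-scored track σ_X = 1. Zero-variance snippets/channels are rejected
(σ = 0 is never inverted).

**Multivariate convention.** For RQE and Shannon the package computes the
univariate entropy per channel and averages entropies across channels.
An alternative reading — averaging univariate *kernels* inside a single
information potential — is a different estimator; the entropy-averaging
form is the one used by the curve pipeline because it is the one defined
operationally by the multiscale algorithm, and it is what the greedy
channel search recomputes per subset.

## Multiscale curves

MEMD is computed over the **entire recording**; entropies are estimated
only on snippets inside the analysis window (default: the trailing 100 s).
Scale modes: `cimf` (default; curves flatten once the cumulative band
covers the preprocessing band — the reason scale 6 is the default
reporting scale at 128 Hz with a 0.5–30 Hz band) or `imf` (per-mode).
Dispersion is the standard error across snippets of one recording; group
summaries across subjects use the standard error across subjects.
Channel subsets can be taken before MEMD (the subset defines the joint
scales, used by the greedy search) or after (one decomposition reused for
all subsets); the choice is an explicit flag. Curves of different native
lengths are harmonized for group display by truncation / last-value
padding to a fixed count (default 15).

## Agreement statistics

Interval Krippendorff alpha is computed from pairable values:
`α = 1 − D_o/D_e`, D_o the within-item mean of squared differences over
ordered pairs weighted by 1/(m_u − 1), D_e the same mean over all pairs of
pairable values. Missing entries are excluded pairwise; all-identical
data gives α = 1 by convention. The block bootstrap draws rater subsets
(default 1000 draws of 5) with replacement. The group comparison is a
two-sided one-sample t-test of a control bootstrap distribution against
the main-group alpha; because bootstrap draws are not independent samples
this p-value is optimistic, and an exact percentile test is provided as an
alternative. The temporal-evolution helper supports both cumulative and
sliding window schedules, since either is defensible; cumulative-from-
start is the default.

## Synchrony

Instantaneous phase is the analytic-signal angle after an optional
zero-phase band-pass; PLV per non-overlapping window (default 200 ms) is
the modulus of the windowed mean phase-difference phasor. Note the small-
sample bias: for independent *narrowband* signals the effective number of
independent phases per window is set by the bandwidth, so 200 ms windows
on, e.g., 4–16 Hz noise sit near PLV ≈ 0.5 rather than 0. Comparisons
against surrogates, which share this bias, are therefore the meaningful
statistic — not raw PLV magnitudes.

IAAFT surrogates alternate spectrum substitution with rank remapping,
ending on a rank step so the value multiset is preserved exactly while the
amplitude spectrum is reproduced to well under 2% RMS on strongly
autocorrelated test signals. Each member of a pair is surrogated
independently (c = 10 surrogates, 1000 iterations by default; `c` is the
ensemble size), destroying cross-signal phase relations while preserving
marginals and spectra; inputs are band-passed to 0.05–30 Hz before
surrogate generation. A window is flagged when the observed PLV exceeds
the surrogate maximum, giving a pointwise type-I rate of about 1/(c+1).

## Synthetic data

The generators define the test-bench conditions:

* Recordings: oscillatory components (optionally AM/FM) plus white, AR(1)
  or pink noise.
* Complexity cohorts: variance-matched mixtures
  `√λ·white + √(1−λ)·AR(1, ρ=0.9)` with the item's level λ planted
  (defaults 0.2 vs 0.8), subject jitter SD 0.05, 3 channels, 30 s at
  128 Hz — long enough for ≥ 6 modes while keeping a full cohort run in
  minutes. Noise-colour mixing was chosen over chaotic maps because it
  yields a monotone, tunable multiscale-entropy ordering with a known
  direction.
* Coupled pairs: band-limited noise driver; the follower copies the
  driver's analytic phase plus von Mises jitter whose concentration is
  obtained by inverting PLV = I₁(κ)/I₀(κ); zero-coupling segments use
  independent noise. The light jitter smoothing needed for the analytic
  phase to track raises measured PLV slightly above the target; p = 1
  (zero jitter) is exact.
* Ratings: item means with unit between-item variance plus rater noise
  whose variance is solved from the finite-sample expectation
  `E[α] ≈ g/(σ_e² + g)`, g = n/(n−1); calibration is within ±0.01 of the
  target at 30 raters × 5 items.

What these generators do **not** emulate: real EEG spectra (1/f shape,
alpha peaks), topographic correlation structure across electrodes,
artifacts, or non-stationarity beyond the planted effects. Passing tests
therefore demonstrate that the estimators and statistics behave as
specified on signals with controlled ground truth — not that any
particular neural effect exists.

## Problem sizes and determinism

Defaults are chosen so that a full synthetic cohort (10 subjects × 2
conditions, 3 channels, 30 s) decomposes and scores in a few minutes on
one core, and the white-noise mode-count study (2 × 5 runs at 30000 and
52000 samples) in about a minute per run. All randomness flows from
explicit seeds; pipeline substreams are derived from one root seed via
SHA-256 of named labels, so every stage is independently reproducible.

## Known limitations

* EMD/MEMD have no variational definition; results depend (mildly) on the
  sifting parameters and direction sampling. The defaults here reproduce
  the dyadic filterbank on white noise, which is the relevant benchmark,
  but other implementations will differ in detail.
* Mode counts for broadband signals are data-driven and vary by ±1 across
  realizations.
* The t-test variant of the group comparison inherits bootstrap
  dependence; use the percentile test when calibrated error rates matter.
* `sosfiltfilt` edge transients affect roughly one filter time-constant at
  each end of a track; analyses of short tracks should discard edges or
  use windows away from them.
* The EDF/BDF reader path depends on `mne` and is exercised lightly in the
  test suite (no EDF writer is available to round-trip fixtures); CSV is
  the canonical tested format.
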