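# Methods

This note documents the models, the fixed constants and the judgment calls
behind `lpcsep`: what is computed, under which assumptions, and what the
synthetic validation does and does not establish.

## Signal model and feature definitions

The analysis treats a preprocessed LFP as a wide-sense-stationary series
adequately summarized by a low-order all-pole (autoregressive) model. The
order-N predictor x̂(n) = Σ a_k x(n−k) minimizes the mean-square error J;
its coefficients solve the Yule–Walker system built from the signal's
autocorrelation. Expectations are replaced by **biased time averages**
r(l) = (1/L) Σ_{n=l}^{L−1} x(n)x(n−l): dividing by L rather than L−l
guarantees a positive-semidefinite Toeplitz system, so the Levinson–Durbin
recursion is well defined and |r(l)| ≤ r(0) always. Signals are real, so
conjugations are vacuous.

Two orders are exposed (higher orders are accepted by the solver for
testing, but the pipeline caps at 2 — beyond that the added separation does
not repay the added computation for this signal class):

* **Order 1.** The scalar state feature is δ = (1 − a₁)·10³. For the
  low-pass field potentials targeted here a₁ sits just below +1, so δ is a
  small positive number that grows with bandwidth (faster autocorrelation
  decay). The sign convention deserves a note: with the predictor form used
  here a₁ ≈ +1, and the equivalent prediction-*error*-filter convention
  carries the opposite sign. δ is defined as (1 − a₁)·10³ precisely so that
  it equals the plotted/tabulated "coefficient × 10³" quantities of the
  narrow-band literature (≈ 2.9 for the narrow preset below) regardless of
  which sign convention a reader assumes.
* **Order 2.** The poles of z² − a₁z − a₂ form a conjugate pair
  A·e^{±jθ} iff a₁² + 4a₂ < 0; then f₀ = θ·fs/2π estimates the dominant
  frequency and A the peak sharpness. Real poles yield no dominant
  frequency (`None`); the degenerate double pole on the negative real axis
  is kept as the conjugate-pair limit at the Nyquist frequency fs/2.
  Note that f₀ is the **pole frequency**, not the spectral argmax: for
  broad peaks (A ≲ 0.97) the all-pole spectrum's maximum is pulled several
  Hz below the pole frequency; the two coincide only in the narrowband
  regime.

The model PSD is S(f) = J·Tₛ / |1 − Σ a_k e^{−j2πfkTₛ}|².

## Preprocessing chain

Order of operations: per-channel bandpass → per-channel unit-power
normalization → channel average. Because every channel is rescaled to unit
power before averaging, the chain is invariant to per-channel amplifier
gain; amplitude units are therefore treated as opaque metadata throughout.
Normalization applies to whatever series is passed — the whole session when
run before segmentation, which is the pipeline's order.

* **Bandpass: 2.5–50 Hz, zero-phase FIR.** The filter is a linear-phase
  windowed-sinc design (Hamming window), length ⌈3.3·fs⌉ rounded to odd
  (3301 taps at 1 kHz), giving ≈1 Hz transition width and ≥40 dB stopband
  attenuation. Zero phase is achieved honestly — one pass of a symmetric
  filter with its known group delay removed by centering the convolution
  (edges implicitly zero-padded) — rather than by forward–backward
  filtering, which would square the magnitude response. Passband sinusoids
  emerge with unit gain and zero lag (verified by cross-correlation).
* **Segmentation.** Non-overlapping, left-aligned epochs from t = 0; a
  trailing remainder shorter than one epoch is discarded, so a 40-min
  session yields 13 three-minute epochs with 60 s unused. Sample counts are
  rounded half-away-from-zero so counts are platform-stable.
* **Expanding windows.** Window k holds the first
  round((init + k·step)·fs) samples (defaults 1 s + 1 s increments). The
  streaming estimator keeps exact running lag products and the sample
  count — no forgetting factor, matching the cumulative window — so the
  model after every update equals the batch fit on the same prefix to
  floating-point accuracy, at O(order) cost per sample.

## Comparator biomarkers

* **Welch PSD**: 2-s Hamming windows, 50% overlap (unstated in the source
  literature; chosen for 0.5 Hz resolution and stable estimates on 3-min
  epochs). Band power is reported as a fraction of total (0, fs/2) power,
  making it gain-invariant.
* **PAC modulation index**: phase from the analytic signal of the
  phase-band-filtered series, envelope from the analytic signal of the
  amplitude-band-filtered series; 18 phase bins of 20° (the de-facto
  standard bin count); index = KL divergence of the normalized phase-binned
  mean envelope from uniform, divided by log 18, hence in [0, 1]. Per-band
  filters are zero-phase FIRs sized to ≥3 cycles of the band's low edge.
  At least 10 cycles of the phase band are required. If the amplitude band
  holds < 10⁻⁴ of total power (e.g. 200–350 Hz on data low-passed at
  50 Hz — a physically empty band) the index is still returned with a
  warning; the floor sits above the ≈3·10⁻⁶ leakage the FIR stopband alone
  contributes. An identically zero envelope is an error.
* **Band definitions.** Grid sub-bands: delta 3–4, theta 5–7, alpha 8–11,
  low-beta 12–19, high-beta 20–30, gamma 31–60 Hz (6×6 = 36 indices).
  Single pairings: beta phase 13–30 / gamma amplitude 50–200 Hz, and
  low-beta phase 12–30 / HFO amplitude 200–350 Hz — the 12–30 Hz "low-beta"
  of the pairing intentionally differs from the 12–19 Hz grid sub-band, as
  both definitions circulate in the source literature.
* **Canonical-correlation composite**: first canonical direction between
  the (signals × 36) index block and a binary condition indicator — with a
  one-column indicator this is a discriminant direction, computed without
  regularization. Requires strictly more signals than features (hence
  3-min epochs, never whole sessions) and a full-rank centered feature
  block; the composite's sign is fixed so the lexicographically second
  condition has the larger mean.

## Classification and statistics

The decision threshold is the midpoint between the closest points of the
two feature sets: the group with the larger median (tie → larger mean) is
"upper", threshold = (min(upper) + max(lower))/2, margin = min(upper) −
max(lower). Margin > 0 ⇔ complete separation. A value exactly at the
threshold classifies as upper. Epochs are pooled across subjects within
condition (4 sessions × 13 epochs → 52 per condition), and the threshold is
fitted on the pooled values.

Rank-sum p-values use the exact enumeration distribution when both groups
have ≤ 10 tie-free observations, else the normal approximation with
continuity correction and midranks. The switch point reproduces both
canonical complete-separation regimes: p = 2/70 ≈ 0.0286 at 4 vs 4 (exact)
and p = 1.54·10⁻¹⁸ at 52 vs 52 (corrected normal). Kruskal–Wallis uses the
chi-square reference with midrank tie correction; for two groups H equals
the squared uncorrected rank-sum z, so the two tests differ only by the
continuity correction (1.54 vs 1.50 ·10⁻¹⁸). All-identical data short-
circuits to H = 0, p = 1. No multiple-testing correction is applied.

## Synthetic data: what it emulates, what it does not

A session is one shared AR(2) source — conjugate poles at radius A and
frequency f₀, unit-variance Gaussian innovations, the first 10/(1−A)
samples discarded as burn-in — observed on 4 channels through independent
additive Gaussian noise. Defaults: fs = 1 kHz, 40 min, 4 subjects per
condition. The condition presets encode the target phenomenon (a narrow
low-beta peak that a treatment shifts up and broadens):

| preset        | A     | f₀ (Hz) | interpretation              |
|---------------|-------|---------|-----------------------------|
| saline-like   | 0.995 | 12.2    | narrow peak, low dominant f |
| levodopa-like | 0.985 | 14.2    | broader peak, higher f      |

Channel noise defaults to 10 dB source-to-noise — a realistic shared-field
to electrode-noise ratio for striatal microwire recordings; the exact value
mainly rescales δ without affecting separability. Seeding: each session's
generator stream derives from (master seed, condition index, subject
index), so any subset regenerates identically.

Deliberately **not** modeled: within-condition subject-to-subject spectral
variability, slow nonstationarity, movement artifacts, line noise, and any
phase–amplitude coupling structure. Two consequences matter for
interpreting the validation. First, passing the end-to-end test shows the
pipeline recovers a known spectral difference through the full chain — it
does not show robustness to real-LFP nuisance structure. Second, because
the condition difference is *purely* spectral and epochs are long, the
beta-power fraction separates the synthetic conditions completely as well
(reaching the same rank-sum floor as the LPC feature); the empirical
finding that beta power fails where LPC succeeds on real recordings
reflects precisely the variability this generator omits. The PAC indices,
which carry no information about a spectral-only difference, do separate
far worse here, as expected.

The coupled test tone is
s(t) = cos(2πf_p t) + 0.5·(1 + depth·cos(2πf_p t))·cos(2πf_a t) + noise;
its amplitude carrier must sit *inside* a grid amplitude band (tests use
45 Hz with 6 Hz phase) for the (theta, gamma) cell to be the grid maximum.
Surrogate nulls for it use envelope permutations — circular time shifts do
not destroy the phase–envelope dependence of a strictly periodic tone.

## Validation problem sizes and known limits

The validation suite uses: 1000 random autocorrelation sets (order 8) for
the Levinson–Durbin vs direct-Toeplitz equivalence (observed ≤ 10⁻¹⁵
relative); 240 one-second increments for streaming-vs-batch (≤ 10⁻¹²); 500
replicates of L = 60 000 for AR(1) recovery (within 3 asymptotic sd,
sd = √((1−a²)/L), in ≥ 99% of replicates for a ∈ {0.5, 0.9, 0.99}); 40
replicates per cell of the {0.9, 0.95, 0.995} × {10, 12, 14, 20 Hz} AR(2)
grid; and 1000 replicates of 13-vs-13 for the null calibration. Null
replicates draw features from 2-s segments with identical parameters on
both sides: the rank-sum test is distribution-free under this exchangeable
null, so the rejection rate (≈5% at α = 0.05) does not depend on segment
length, and short segments keep the experiment cheap.

Known limitations:

* **Pole-frequency spread at broad bandwidth.** The asymptotic covariance
  of the Yule–Walker AR(2) estimates implies a pole-frequency standard
  deviation of 0.34–0.57 Hz at A = 0.9 with 60 s of 1 kHz data, so
  "within 0.5 Hz" recovery cannot exceed ≈62–86% there no matter the
  implementation; finite-sample pole shrinkage (≈−0.3 Hz at A = 0.9)
  lowers it further. At the radii this pipeline actually encounters
  (≥ 0.985) recovery is effectively 100%. The validation reports the
  aggregate rate over the full grid (~82–88%) rather than hiding the
  broad-bandwidth corner.
* **Constant/degenerate inputs.** The biased autocorrelation of a constant
  series is r(l) = c²(1−l/L) — a well-conditioned system with a₁ ≈ 1 — so
  "constant input" is not an error at the solver level; genuinely singular
  systems (condition number ≥ 10¹²) are rejected with a conditioning
  message, as are autocorrelations whose reflection coefficients reach
  magnitude 1.
* The normalization-before-averaging order and pooled (not per-subject)
  thresholding are fixed design choices; both alternatives are reasonable
  on real data and neither is exposed as an option.
* File I/O is CSV + JSON sidecar with 9 significant digits — lossless for
  the feature scales used here, not for adversarial float round-trips.
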