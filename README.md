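# lpcsep

Linear-predictive-coding (LPC) biomarkers for separating brain states in
local field potentials (LFPs).

Adaptive deep-brain stimulation needs a trigger signal that can be computed
from ongoing neural activity in real time, with as few parameters and as
little computation as possible. `lpcsep` implements such a trigger: it fits
a first- or second-order autoregressive (AR) model to a preprocessed LFP and
reduces minutes of multichannel data to one or two scalars that distinguish
pharmacological brain states — for instance saline- versus levodopa-treated
sessions in a dopamine-depleted rodent. The package is aimed at
electrophysiologists and neural-engineering researchers prototyping
closed-loop biomarkers, and at anyone who needs a compact, streaming
spectral-shape feature for 1 kHz field-potential data.

## The model

An order-N linear predictor approximates each sample from its N predecessors,

    x̂(n) = Σ_{k=1..N} a_k x(n−k),

with coefficients chosen to minimize the mean-square error
J = E[|x(n) − x̂(n)|²]. The optimum solves the Yule–Walker system
**R**_N **a** = **r**_N built from the autocorrelation
r(l) = E[x(n)x(n−l)] (estimated here by biased time averages), which the
Levinson–Durbin recursion solves order-recursively in O(N²).

* **Order 1** — the single coefficient a₁ tracks the lag-1 autocorrelation,
  i.e. overall signal bandwidth. The reported scalar feature is
  δ = (1 − a₁)·10³: small and positive for strongly low-pass LFPs, larger
  for broader-band states.
* **Order 2** — the predictor's poles are the roots of z² − a₁z − a₂. A
  conjugate pair A·e^{±j2πf₀Tₛ} estimates the dominant frequency f₀ (pole
  phase) and peak sharpness (radius A).

Before fitting, each channel passes a zero-phase FIR 2.5–50 Hz bandpass, is
normalized to unit power, and channels are averaged into one series per
session. Sessions are analyzed whole, in fixed epochs, or through expanding
windows updated second-by-second by a constant-cost streaming estimator.

Alongside the LPC features the package implements the established
comparator biomarkers — the beta-band (12–30 Hz) power fraction, Welch
spectra, phase–amplitude-coupling (PAC) modulation indices for standard
band pairings, the 6×6 grid of 36 indices over sub-bands of 3–60 Hz with a
canonical-correlation composite — plus a midpoint-threshold classifier,
Wilcoxon rank-sum / Kruskal–Wallis statistics, and a seeded synthetic-LFP
generator (AR(2) source + per-channel noise) that emulates two conditions
differing in dominant frequency and bandwidth.

## Worked example

`examples/01_simulate_and_separate.py` generates two 5-minute conditions
(two subjects each), extracts the order-1 feature per 1-minute epoch, and
fits the decision threshold:

```
saline feature:   2.999 +/- 0.025  (n=10)
levodopa feature: 4.016 +/- 0.035  (n=10)
threshold 3.512, margin 0.938, complete separation: True
rank-sum p = 1.08e-05, Kruskal-Wallis p = 0.000157
```

The narrow-band ("saline-like") state sits near δ ≈ 3.0, the broader-band
("levodopa-like") state near δ ≈ 4.0; the positive margin means a single
fixed threshold classifies every epoch correctly. The other examples cover
dominant-frequency estimation from the order-2 poles, second-by-second
streaming updates, the comparator biomarkers, and the two regimes (exact
vs normal-approximation) of the rank statistics.

A thin CLI mirrors the pipeline stages:

```bash
lpcsep simulate --out data/ --seed 1          # synthetic two-condition dataset
lpcsep features data/*.csv --method lpc1 --epoch-min 3 --out features.csv
lpcsep classify features.csv --out separation.json
lpcsep compare features.csv --out report.csv  # p-values per method
```

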