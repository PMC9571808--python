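# Methods

## The problem and the model

A catalytic-gate field-effect gas sensor changes its drain current when
analyte molecules adsorb at the gate. Operated isothermally it is
sensitive but not selective; operated in a repeating temperature cycle
("dynamic mode") it yields, at each plateau temperature, a differently
weighted response to each analyte — a virtual sensor array in one device.
`cyclenose` implements the full analysis chain for such a device and a
synthetic sensor model that replaces the hardware.

### Temperature program

Default: five plateaus descending 360 → 240 °C in 30 °C steps, 22 s per
plateau, 10 Hz sampling → 1100 samples / 110 s per cycle. The descending
order and all geometry are configurable (`TemperatureProgram`); feature
counts scale with cycle length. 22 s is long enough for the thermal
transient (τ_T = 2 s by default) to die out within each plateau.

### Gas-response model

Steady-state relative response (percent) of gas *g* at plateau temperature
*T* and concentration *c*:

    R(g, T, c) = A(g, T) · (c / c_ref)^β

* `A(g, T)` — per-plateau amplitudes in % at `c_ref` = 1000 ppb,
  interpolated over temperature. Defaults (240→360 °C):
  CH₂O (5, 8, 11, 13, 14), CH₂O₂ (4, 6.5, 8.5, 7.5, 6),
  CH₃COOH (1.5, 2.5, 3.5, 4.5, 5.5). Two modelling commitments: the
  ordering CH₂O > CH₂O₂ > CH₃COOH holds at every plateau (formaldehyde is
  the most, acetic acid the least reactive on such gates), and each gas
  has its **own temperature profile** (monotone rise, mid-range peak, weak
  rise respectively). The second point is essential: temperature-cycled
  operation discriminates gases precisely because their per-plateau
  response patterns differ — amplitude profiles proportional across gases
  would make standardized cycle shapes nearly collinear and the virtual
  array uninformative, which would misrepresent the class of device being
  emulated.
* `β = 0.7` — sub-linear adsorption isotherm exponent (saturation sets in
  toward the top of the 250–3000 ppb range); shared across gases.
* Response sign: gas exposure *decreases* the current by default
  (configurable; the relative response uses an absolute value, so the
  analysis is sign-agnostic).
* Transients: first-order lags, τ_gas = 60 s at gas switches, τ_T = 2 s at
  temperature steps. Both may be set to 0, making the simulator an exact
  realization of the isotherm — the oracle tests exploit this.
* Baseline current: `I₀(T) = 100 · exp(0.3 (T − 300)/100)` arbitrary
  units — a smooth, featureless function of temperature.
* Drift: linear multiplicative drift, 0.5 %/h by default, plus an optional
  random-walk term (off by default). Small on purpose: per-cycle
  auto-scaling is supposed to remove it, and the tests show that it does.
* Noise: multiplicative lognormal with sd 0.1 % of the local baseline.
  Lognormal keeps the current strictly positive at any noise level while
  being indistinguishable from additive Gaussian noise at small sd.

### Study layout

One exposure = SA baseline → gas at one concentration → SA recovery, each
phase a whole number of cycles; one simulated trace per exposure, with
concentration order randomized within each gas (avoids sequential memory
artefacts). Defaults: 10 baseline / 12 exposure / 4 recovery cycles. The
`demo` fixture scales to 4/8/3 cycles with the first 2 cycles of each
phase discarded as settling, giving 6 observations per (gas, level), 42
per gas over 7 levels, plus 42 SA observations from baseline phases — 168
observations, matching the scale of a realistic bench campaign of about
45 observations per gas and about 170 total.

## Preprocessing

Order: **smooth, then standardize** (the reverse changes the result; a
test pins the order). Savitzky–Golay defaults: window 11 samples (1.1 s),
polynomial order 3 — suppresses sampling-rate noise, passes the 22 s
plateau structure and any cubic trend untouched. Auto-scaling uses the
(n−1)-denominator sample SD and the ×100 convention, so standardized
cycles have mean 0 and sample SD 100; a constant cycle raises a
degenerate-input error. Cycle phase tags (baseline / exposure / recovery)
follow a majority rule over samples with ties resolved toward the later
phase, so a cycle straddling the gas switch counts as exposure exactly
when ≥ 50 % of its samples are under gas. Virtual sensors average the full
plateau window by default; a `window_fraction` option uses only the
trailing part to exclude the thermal transient.

## Features

Per standardized cycle, five families with contiguous, non-overlapping,
half-open windows that tile the cycle exactly:

| family  | window | count (1100 @ 10 Hz) | definition |
|---------|--------|----------------------|------------|
| means   | 2 s    | 55  | arithmetic mean |
| slopes  | 0.5 s  | 220 | OLS slope, signal units/s |
| FFTs    | 5 s    | 22  | magnitude of one DFT bin, unnormalized |
| integral| cycle  | 1   | trapezoid vs time, units·s |
| lifting | cycle  | 1   | last − first sample |

The FFT scalar is the **first non-DC bin** by default: the DC bin would
duplicate the window means, and the slowest oscillatory component is the
most complementary single summary; the bin index is configurable since
other conventions are defensible. The slope estimator is OLS over the
5-sample window rather than an endpoint difference (noise-robust, same
expectation). Lifting is taken as last − first, so a positive lifting
means the cycle ends above where it started; the opposite sign convention
would only flip the feature's sign and nothing downstream.

## Selection and models

Sequential forward selection, plain greedy (no floating/backtracking):
at each step add the feature maximizing the cross-validated criterion of
the enlarged subset; ties break to the lowest column index; the CV fold
assignment (from the seed) is the only randomness. Criterion: stratified
10-fold CV accuracy of the chosen SVM for classification tasks, 10-fold CV
R² of PLSR for quantification. Features are z-scored with training-fold
statistics only (no leakage). Default subset size 8. Concentration tasks
re-run SFS with their own criterion rather than reusing the gas-identity
subset — the features that separate gases need not be the ones that track
concentration.

SVM: quadratic polynomial kernel by default (coef0 = 1, C = 1,
one-vs-one multi-class), linear available. Out-of-fold predictions from a
stratified 10-fold CV populate the confusion matrix; per-class rates are
the diagonal of the row-normalized matrix. Every class must have at least
as many members as folds; violating that is an error, not a silent
refold. For the demo-scale per-gas concentration task (6 observations per
level) the pipeline therefore uses 6 stratified folds — with so few
observations per level a 10-fold stratified split does not exist, and we
prefer keeping stratification over keeping the fold count.

LDA projects the z-scored selected features onto ≤ (classes − 1)
discriminant functions (SVD solver; on a singular within-class scatter it
falls back to shrinkage LDA and logs the fallback).

PLSR: 80/20 train/test split stratified by concentration level, z-scoring
fit on the training part; number of latent components chosen on the
training part by 10-fold CV RMSE with the one-standard-error rule
(smallest model within one SE of the optimum), capped by the training
rank; R² (1 − SS_res/SS_tot) and RMSE reported on the held-out part.

## Reproducibility and numerics

Every stage takes an explicit seed; the pipeline derives per-stage seeds
from the master seed via a seed sequence, so a run is bit-identical given
its config (the manifest records SHA-256 hashes of all artifacts).
Degenerate inputs fail loudly: constant cycles, zero-variance regression
targets, classes smaller than the fold count, unknown gases, plans shorter
than one cycle.

## Problem sizes

The shipped configurations are desk-scale by design: the `demo` fixture
(168 observations, 21 exposures of 15 cycles) runs the complete analysis
in a few minutes on one core, and `tiny` (2 gases × 2 levels) exercises
the full pipeline in seconds for smoke tests.

## What the simulator does and does not show

The generator reproduces the statistical structure the analysis relies on:
gas- and temperature-dependent relative responses with realistic
magnitudes, sub-linear concentration dependence, first-order transients,
drift, and noise. It does **not** model adsorption kinetics on Ir-gate
surfaces, humidity (real sensors cross-respond to water vapor), gas
mixtures, sensor-to-sensor variation, or slow aging beyond linear drift.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and self-consistent — that the pipeline recovers what the
generator put in under the stated conditions — not that a physical sensor
achieves these accuracies; published hardware results (e.g. ~91 %
four-class validation accuracy on real measurements) are the appropriate
external reference and are documented, not targeted, here.

## Known limitations

* Cycle segmentation assumes the trace starts on a cycle boundary (true
  for simulated traces); hardware data with jittered temperature control
  would need alignment first, which is out of scope.
* The per-gas concentration classifier treats levels as unordered classes,
  as is conventional for confusion-matrix reporting; an ordinal model
  would use the level structure.
* With 42 observations per gas the PLSR test split holds out only 9
  points; R²/RMSE on it are correspondingly noisy across seeds.
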