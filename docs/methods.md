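# Methods

This note documents the statistical procedures implemented in `irquant`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic validation does and does not establish.

## Fluorescence quantification

### Measurement model

A tissue half of mass `m` (g) is homogenized in `V` mL of lysis buffer and
read as a 1:2 serial dilution series. Well `k` holds concentration
`C_lysate / step_factor^k` (index 0 = neat lysate; an optional per-sample
`predilution` factor covers workflows that pre-dilute before plating). The
scanner response is assumed linear in concentration *within a limited
range*: above it, concentration quenching depresses the signal per
fluorophore, and at the detector ceiling the reading is truncated
outright. Both effects bias a naive readout downward, which is the failure
mode the dilution design exists to remove.

### Linear-range selection

The linear range of each series is delimited by a successive-ratio walk:

1. Exclude every saturated well (intensity ≥ `detector_ceiling`); any well
   more concentrated than a saturated well is also excluded (the series is
   physically broken there).
2. Starting from the most dilute surviving well and moving toward the
   concentrated end, retain wells while each successive intensity ratio
   lies within `step_factor^gap · (1 ± linearity_tolerance)`. The first
   violating well and everything more concentrated is excluded
   (`nonlinear_high`) — the onset of quenching seen from the clean side.
3. Require at least `min_linear_wells` survivors, else the sample is
   reported unquantifiable rather than silently underestimated.

The rule is local and assumption-light: it needs no model of the quench
curve, only that dilution eventually restores proportionality. Tolerance
(default 0.15) trades sensitivity to curvature against robustness to well
noise: with multiplicative well noise of CV `c`, a ratio fluctuates with
CV ≈ `c·√2`, so the default tolerates well CVs up to roughly 5% at the
±2σ level. The minimum of 3 wells ensures the retained range itself
carries internal replication.

A well below the limit of detection does **not** terminate the walk: with
multiplicative noise a dim well still has a valid ratio, and terminating
there would conflate sensitivity with linearity. Dim wells lose averaging
rights instead (below).

### Calibration and inverse prediction

The calibration curve is ordinary least-squares of intensity on
concentration over the standard (injected probe) dilution series, after
the standard series itself passes the same saturation/linear-range
selection — a quenched top standard must not bend the line. Classical
(inverse-prediction) calibration is used: `C = (I − intercept)/slope`.
Unweighted OLS is adequate because the retained standards are confined to
the detector's proportional range; weighted fitting is a possible
extension but is not implemented.

The limit of detection is the IUPAC-style 3σ rule on the intensity scale:
`LOD = intercept + 3·residual SD`. Inversion never raises: readings below
the LOD are flagged, readings below the intercept clamp to zero
concentration. Per-well lysate estimates `C(k)·step^k` are combined by
unweighted mean over retained, above-LOD wells — within the linear range
the per-well estimates are homoscedastic on the relative scale, so equal
weights are appropriate — and their coefficient of variation is reported
as a per-sample quality metric. If every retained well is below the LOD
the sample reports 0 with a `below_lod` flag.

### %ID/g

`%ID/g = 100 · C_lysate·V / (dose·m)` with the injected dose defaulting to
106 µg (a typical single antibody injection). Each tissue half uses its own
dissection weight; no whole-organ reconstruction is attempted.

## Gamma reference

`%ID/g = 100 · (cpm·2^(t/T½)) / (cpm_std·2^(t_std/T½)) / m`, with
T½ = 78.4 h (⁸⁹Zr) by default. Giving the sample and the injected-dose
standard their own elapsed times makes both conventions expressible: a
simultaneously counted standard (the two factors cancel) and an
injection-time-referenced standard. The standard is an explicit input
rather than a hidden detector-efficiency constant.

## Summaries and per-organ comparison

Organ-level results are mean ± SEM (sample SD / √n; SEM omitted at n = 1).
The per-organ between-method test is a two-sided **paired** t-test on
per-specimen (gamma − IR) differences — the two halves of one organ are
natural pairs — with significance tiers marked at p < 0.01 (**) and
p < 0.001 (***). The pairing choice is an assumption (recorded in output
metadata by the mark tiers used); a Welch unpaired fallback is available
via `comparison_test`. No multiple-testing correction is applied across
organs by default, matching per-organ reporting practice; Bonferroni and
Benjamini–Hochberg are available via `p_adjust`. Identical paired values
give p = 1 by convention; a constant nonzero shift with zero variance
gives p = 0 (infinite t).

Imaging tumor-to-normal ratios are simple ROI-mean quotients, summarized
as mean ± SD over mice; segmentation is out of scope and ROI means are
inputs.

## Agreement analysis

For pairs `(x_gamma, x_ir)` with difference `d` and average `a` (pairs with
`a ≤ 0` are excluded with a warning — they cannot be log-transformed):

1. **Bias.** `bias = mean(d)`.
2. **Magnitude.** OLS of `d` on `log a`; if the two-sided slope p < α the
   bias line is the fitted log-linear line, otherwise the constant mean.
3. **Variation.** OLS of `|d − bias_line(a)|` on `log a`; if the slope is
   significant the limits model is log-linear, else constant.
4. **Limits.** For a centred Gaussian residual, `E|r| = σ·√(2/π)`, so the
   predicted mean absolute residual `m(a)` is scaled by `√(π/2)` to a
   standard deviation and the 95% limits are
   `bias_line(a) ± 1.96·√(π/2)·m(a)`, with the half-width clamped at 0
   where a log-linear `m(a)` extrapolates negative.

z = 1.96 (not a t quantile) follows conventional 95% limits-of-agreement
practice and is configurable. The log base (natural by default) only
rescales the reported regression coefficients; the limits themselves are
base-invariant, and a property test holds this to 1e-10.

Degenerate inputs are resolved before the library regression: a constant
response means no evidence of trend (slope 0, p = 1); a constant regressor
(`log a` without variance) is an error; a perfectly collinear fit gives
p = 0. Fewer than 3 usable pairs is an error.

## Synthetic studies

The generator emulates the full measurement chain of a 6-mouse,
two-tumors-per-mouse, twelve-organ study with known latent truth:

- **Uptake.** Organ-level %ID/g drawn lognormally around configurable
  organ means (tumor 15, liver 20, muscle 1.2 %ID/g, …; an
  antibody-probe-like pattern 24 h post-injection) with between-mouse CV
  0.25; each organ splits into an IR half and a gamma half with
  independent mean-1 lognormal heterogeneity factors (CV 0.10), because
  intra-organ heterogeneity is the irreducible disagreement between the
  halves.
- **Fluorescence.** Response `gain·C/(1 + C/K)` — the simplest
  one-parameter saturable departure from linearity; at `C = K` exactly
  half the linear signal is lost. Defaults: gain 8000 AU/(µg/mL),
  K = 200 µg/mL, multiplicative lognormal well noise CV 0.02, 16-bit
  ceiling 65535 AU, 8 wells per series, 0.5 mL homogenization volume,
  standards from 2 µg/mL in 1:2 steps. With these values a liver-like
  lysate (~25–50 µg/mL) saturates its top wells while the retained range
  carries at most ~2% residual quench — the regime the method is designed
  for. The analysis pipeline never assumes the saturable form, so the
  generator is a fair adversary.
- **Gamma.** Measured %ID/g = half truth + 0.63 (a constant
  calibration-type offset between the labels) + Gaussian noise with SD
  `0.05 + 0.15·ln(average)`, clamped at 0 — building in the log-linear
  heteroscedasticity that the agreement module must detect. Counts are
  back-computed against a 5·10⁵ cpm standard with staggered count times so
  decay correction is exercised end-to-end.
- **Reproducibility.** One study seed is split into an independent stream
  per (mouse, specimen) via seed sequences, so extending the organ panel
  or mouse count leaves existing draws untouched; identical seeds give
  byte-identical CSVs.

`simulate_pairs` generates paired samples directly (log-uniform averages
on 1.5–30 %ID/g — the lower bound keeps the default log-linear SD
positive) for focused agreement tests.

### What the synthetic validation shows — and does not

Passing tests establish that the estimators are correct against
brute-force oracles, that linear-range selection removes the
underestimation that quench + saturation otherwise cause (≈ −24% at
liver-like concentrations with the defaults), that the full pipeline
recovers configured organ means and the configured between-method offset,
and that the limits of agreement attain their nominal 95% coverage under
log-linear heteroscedasticity. They do **not** establish performance
against real plate data: the generator has purely multiplicative well
noise (no additive background floor, so dim-well ratios stay clean),
no inter-plate variation, no pipetting serial-correlation down a dilution
column, and a single quench functional form. The LOD behaves differently
under an additive noise floor than under this multiplicative model.

## Numerical and design choices

- Validation errors are typed (`FormatError`, `ValidationError`,
  `LinearRangeError`, `FitError`, `DomainError`, `EstimationError`) and
  study-level runs skip-and-warn on per-sample failures instead of
  aborting.
- The organ vocabulary is advisory: unknown organs warn and pass through.
- Whole-study problem sizes used by tests and `scripts/acceptance.py`:
  one 6-mouse study (78 specimens) for end-to-end recovery; 500 replicate
  series for linear-range bias; 10⁴ pairs for limits coverage; 10⁵ pairs
  for the half-normal constant — sizes at which the Monte-Carlo error of
  each check is several times smaller than its tolerance.
- Known limitations: no 4PL/sigmoid calibration, no weighted calibration
  fit, no repeated-measures limits of agreement, no plate-image
  processing, no inter-plate correction factors (an optional per-plate
  blank subtraction exists but is off by default).
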