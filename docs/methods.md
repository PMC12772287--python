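# Methods

This note documents the statistical model behind `phagekinetics`, the
conventions it fixes where the field's practice is genuinely ambiguous, the
generative model of its simulator, and what the test suite does and does
not demonstrate.

## Counting model and titer uncertainty

A plaque assay plates a volume `v` (mL) of a sample diluted `d`-fold; the
number of plaques `c` is modeled as Poisson with mean `C·v/d`, where `C` is
the titer (PFU/mL). The point estimate is `C = c·d/v` and its standard
uncertainty is taken on the count scale as

    σ_count = max(√c, 1.2),    σ_C = σ_count · d / v.

The floor of 1.2 counts prevents a single-plaque plate (√1 = 1) from
claiming a tighter relative error than counting statistics at that scale
can support; it operates on the count scale *before* scaling by dilution
and volume (a floor on relative error would be the other defensible
reading; the count-scale reading is adopted and fixed here). Plates with
zero plaques or too many to count (TNTC) carry a status but no numeric
value: a zero tells you only that `C·v/d` is small, and a TNTC plate only
that it is large, so neither may enter a weighted average of titers.

Two sequential dilutions of the same replicate culture are treated as
independent measurements (six attempted per timepoint with triplicate
cultures). Their counts are independent Poisson draws given the titer, so
this is exact under the counting model; it ignores shared pipetting error
upstream of the split, which the model does not represent.

## Weighted aggregation

Per timepoint, quantitative estimates are combined with weights equal to
the inverse relative error, `w_i = x_i/σ_i` (≈ √c_i under the counting
model, so high-count plates dominate). The weighted mean is `m = Σw_i x_i /
Σw_i`. For the weighted SD, two conventions circulate in common R helpers
and the source of a given analysis rarely says which was used; both are
implemented behind `ExperimentConfig.sd_convention`:

* `"normalized"` (default): rescale weights to sum to n, then
  `sd² = Σw′_i(x_i − m)²/(n − 1)`. Invariant to the overall weight scale.
* `"frequency"`: treat weights as effective frequencies,
  `sd² = Σw_i(x_i − m)²/(Σw_i − 1)`.

A timepoint with a single quantitative measurement reports that
measurement's own σ as its SD, preserving a usable uncertainty for
propagation (reporting 0 would claim certainty; reporting nothing would
break the downstream chain).

## Jackknife outlier screen

Screening runs only when the weighted CV (SD/mean) exceeds 0.8 **and** at
least four measurements are quantitative — a high-variance timepoint with
enough data to judge influence. For each measurement `i`, with `(m, s)` the
full weighted mean/SD and `(m₋ᵢ, s₋ᵢ)` the leave-one-out values:

    A_i = |(m − m₋ᵢ)/m₋ᵢ|      (influence on the mean)
    B_i = |(s − s₋ᵢ)/s|        (contribution to the spread)

A measurement is an outlier only if *both* exceed 0.5 strictly (a value at
exactly the threshold is kept). Flagged measurements are removed and the
summary recomputed once; the screen is single-pass by design — it is an
influence diagnostic, not an iterative trimming procedure, and iterating it
on 4–6 values would hollow out small samples. Every screened measurement's
(A, B) pair and flag is written to the report's outlier ledger, so an
exclusion is always auditable back to its plate.

## Error propagation

All derived quantities (free fractions, infected cells, burst sizes,
pointwise k) carry first-order (delta-method) uncertainties assuming
independent operands: quadrature of absolute σ for sums/differences, of
relative σ for products/ratios, `σ(ln x) = σ_x/x`. Correlated operands are
out of scope; expressions that reuse a measured quantity treat the
occurrences as independent. First-order propagation is accurate to ~1% for
relative errors up to ~5–8%, but the exact SD of a ratio with a noisy
denominator grows faster: second-order terms inflate it by roughly
`3(σ_y/y)²`, i.e. ~3% at a 10% denominator error. The test suite measures
this against Monte-Carlo rather than hiding it; analyses whose denominators
(e.g. I0) carry ≳10% relative error should read the burst-size σ as a
mild underestimate.

## Welch comparisons from summary statistics

Condition comparisons use Welch's unequal-variance two-sample t-test
computed from (mean, SD, n) triples, with Welch–Satterthwaite degrees of
freedom left unrounded. The quantities being compared (fitted k with its
SE, burst size with its propagated σ) have no intrinsic sample size for
this test, so `n` is an explicit caller argument and is recorded in the
report next to the p-value; a p-value without its n is not reproducible.
When both SDs are zero the statistic is undefined and the package raises
rather than reporting p = 0.

## Adsorption model and fit

The first-order adsorption model is `Pt/P0 = exp(−kNt)` with `N` the host
density (CFU/mL, treated as exact by default; an optional σ_N enters k_se
in quadrature). `P0` is the *measured* free-phage mean at the earliest
sampled time, not the nominal inoculum titer — the model's initial
condition is what was actually in the tube at t0. The fit is unweighted OLS
of `ln(Pt/P0)` on `t` over a configured window (the window is a config
input because the informative range differs between conditions); a
σ-weighted WLS variant is available behind a flag but is not the default,
since with near-constant counts per timepoint the weights are nearly equal
and OLS keeps the estimator transparent. Because P0 noise shifts every
log-fraction equally, it is absorbed by the intercept and does not bias the
slope. For a two-point fit the slope SE has no residual degrees of freedom
and is reported as 0.

## One-step growth analysis

`T0` and `F0` are the total and free titers at the first post-transfer
sampling time; since both are measured in the same hundredfold-diluted
culture, no dilution correction enters `I0 = T0 − F0` or `B =
plateau/I0` (and B is invariant to any common rescaling of post-transfer
titers). `F0 ≥ T0` raises an assay-failure error rather than warning: a
non-positive infected-cell count means the experiment, not the analysis,
failed.

Plateau and baseline are aggregates of whole-timepoint summaries, weighted
by each timepoint's inverse relative error (mean/SD) — the same weighting
philosophy one level up. Latent-period onset is operationalized as the
earliest sampled time with

    mean(t) > baseline + z·√(baseline_sd² + sd(t)²),   z = 2 by default,

replacing the visual "first clear evidence of burst" judgement with a
configurable rule whose parameters are logged in the report. Onset is
resolved only to the sampling grid, and the default z = 2 is a one-sided
~2.5% false-trigger rate per timepoint under normal errors.

## The simulator

The generator is a generative twin of the analysis assumptions, not of a
real bench assay in full:

* Adsorption: expected titer `C(t) = P0·exp(−k_true·N·t)`; defaults
  N = 10⁸ CFU/mL, MOI 0.1 (P0 = 10⁷ PFU/mL), k_true = 2×10⁻⁹ mL/min,
  sampling every minute over 0–10 min, triplicate cultures.
* One-step: deterministic lysed fraction r(t) = 0 before the latent period
  (28 min default), linear ramp to 1 over 20 min, then
  `free = F0 + B·I0·r`, `total = free + I0·(1 − r)` with F0 = 10⁵ PFU/mL,
  I0 = 10⁶ /mL, B = 117; sampling every 5–10 min to 90 min. Pre-burst,
  E[total] − E[free] = I0 exactly.
* Plating: each (time, replicate, dilution) draws an independent Poisson
  count with mean `C·v/d`; counts ≥ 400 are emitted as TNTC and zeros as
  zeros, exercising both censoring paths. Dilutions default to "auto": the
  smallest power-of-ten dilution whose expected count is ≤ 300, plus the
  next tenfold — the serial-dilution choice a bench scientist makes to land
  the better plate in the countable 30–300 range.

What it deliberately omits: pipetting/efficiency variance beyond Poisson
(so real data may be overdispersed relative to the model the weights
assume), per-cell lysis-time distributions (the ramp is deterministic, so
rise-shape inference is not exercised), resistant subpopulations, and
lysogeny. Parameter-recovery results therefore demonstrate correctness of
the estimators under the stated counting model, not robustness to
overdispersed real-world plating.

## Verification by parameter recovery

With 500 seeded simulated assays at the defaults above, the pipeline
recovers k with ~2% median relative error and 1.96·SE interval coverage
near 0.95, and recovers B = 117 with ~5% median relative error (the
acceptance script recomputes both). The 11-point default sampling grid
gives the OLS slope interval enough residual degrees of freedom that the
1.96 normal multiplier is close to nominal; with many fewer timepoints the
same multiplier would undercover and a t-quantile would be needed.

## Numerical conventions and degenerate inputs

* Measurements with σ = 0 (exact values) dominate a weighted aggregate:
  the aggregate is the plain mean of the exact values with σ = 0, avoiding
  infinite weights.
* Jackknife flagging comparisons are strict (>), so threshold ties are
  kept; the screen refuses to run with fewer than two quantitative values.
* Welch df is never rounded; p is clipped to [0, 1].
* Table round-trips are bit-exact: reports serialize floats at full repr
  precision, and the canonical CSV schema preserves TNTC markers.

## Known limitations

* No overdispersion modeling beyond the 1.2-count floor; no
  most-probable-number estimation for heavily censored series.
* No eclipse-period estimation or rise-rate modeling in one-step analysis.
* Propagation assumes independence; covariances (e.g. between T0 and F0
  measured from the same culture) are ignored.
* Published burst/onset values from comparable bench experiments cannot be
  reproduced without their raw plate counts; verification here is by
  simulation and recovery, and printed summary pairs in the literature are
  sometimes internally inconsistent (e.g. the same burst size quoted with
  two different SDs), which only raw counts could resolve.
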