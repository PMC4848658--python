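# Methods

## Prediction equations

The registry stores the five published linear ASM predictors with their
coefficients transcribed literally; `registry_self_test()` diffs the live
registry against a separate literal transcription so a typo cannot survive
silently. All computation is at full floating precision; kg values are
rounded to 2 decimals only at report serialisation.

Conventions that the source literature leaves ambiguous, and how this
package resolves them:

* **Resistance-index direction.** One published footnote defines the
  resistance index as R/Ht², but that reading yields absurd (near-zero or
  negative) muscle masses; the explicit Ht²/resistance term printed in the
  Kyle equation, and the fact that the cm-based Ht²/R reading reproduces
  the published male cohort mean predicted ASM to within 0.4 kg (plug-in
  25.12 vs 24.74 kg), identify the footnote as a typographic inversion.
  The package uses RI = (height in cm)²/R (cm²/Ω) for every equation and
  records both readings here. The residual 0.4 kg gap between the plug-in
  value and the cohort mean is the expected Jensen effect: the mean of the
  nonlinear index Ht²/R is not the index of the means.
* **Height units.** The API takes height in metres (the unit in which
  cohort tables report it); conversion to centimetres happens inside
  `impedance_index` and nowhere else. The CSV reader accepts cm input via
  `--height-unit cm`.
* **Yoshida impedance index.** Its denominator is not defined in the
  validation literature. Default: Z = √(R² + Xc²) at 50 kHz
  (`yoshida_index="z"`), switchable to R; the active convention is emitted
  in every report's provenance block. At typical Xc/R ratios the two differ
  by well under 1% of the index.
* **Kim out of provenance.** The Kim equation was developed on a
  multi-frequency instrument; evaluating it on single-frequency 50 kHz data
  is supported (as validation studies do) but every Kim cell carries a
  provenance warning flag.
* **BMI bands.** underweight < 18.5 ≤ normal < 25.00 ≤ overweight < 30.00 ≤
  obese (kg/m²); boundary values go to the higher band, 18.5 is normal.
  Note that narrative usage of "overweight" as BMI ≥ 25 (including obese)
  exists in the literature; the tabular 25.00–29.99 convention is what the
  pipeline implements.

## Agreement statistics

Differences are oriented predicted − reference throughout, so negative ME
means the equation underestimates the criterion. (Published tables are not
always internally consistent on this sign — e.g. a reported ME of −1.09 kg
alongside limits of agreement centred at +1.09; this package keeps one
orientation and does not emulate such flips.)

* ME = mean(d); 95% CI = ME ± t₀.₉₇₅,ₙ₋₁·SD(d)/√n; p from the paired
  (equivalently one-sample) t-test.
* RMSE = √(mean d²) with the 1/n mean square; SD(d) uses the n−1
  denominator, giving the exact identity RMSE² = ME² + SD(d)²·(n−1)/n.
* RMSE CI: published validation reports rarely state their method, so the
  default is a delta-method interval on the mean square
  (MSE ± t·SD(d²)/√n, endpoints square-rooted, lower endpoint floored at
  0), with a seeded percentile bootstrap (2,000 resamples) available as a
  cross-check; `compare(..., bootstrap_check=True)` attaches the bootstrap
  interval whenever the two disagree by more than 10% of the RMSE.
* Limits of agreement use the conventional fixed 1.96 multiplier, not a
  t-quantile.
* Degenerate variance (all differences equal) collapses the ME CI to a
  point, sets p to 0 or 1 by whether the ME is nonzero, and flags the
  result; Pearson correlation on a constant series raises rather than
  returning NaN.

No regression-based agreement (Deming, Passing–Bablok) and no
proportional-bias slope testing are provided, and no multiple-testing
correction is applied across the equation × stratum grid — matching the
practice of the validation studies this mirrors; both omissions are
deliberate scope limits.

## Validation pipeline

`run_validation` partitions the cohort by total, sex (men/women) and the
four BMI bands — partitions are exhaustive and disjoint within a scheme,
with fixed label order — and computes a full agreement result per
(equation, stratum). Records without a reference ASM are an error listing
the offending ids, not a silent drop. Strata with n < 2 carry an explicit
insufficient-n marker; strata with n < 20 are computed but flagged as
unstable (validation studies do report n = 5 strata, with the same caveat).
Reports (TSV/JSON/Markdown) are byte-deterministic for fixed inputs and
always carry a provenance block: package and registry versions, index
conventions, scheme list, config hash, and the generator seed when the
input is synthetic.

## Synthetic cohort generator

The generator emulates the structure of a sex-stratified adult validation
cohort. Per sex, (age, height, weight, resistance, reactance) are drawn
from a truncated multivariate normal whose default means/SDs equal the
published cohort moments (men: 48.0 (17.0) yr, 1.8 (0.1) m, 85.3 (16.0) kg,
456.1 (47.9) Ω, 54.3 (8.4) Ω; women: 52.7 (14.7) yr, 1.6 (0.1) m,
70.6 (16.7) kg, 571.9 (76.9) Ω, 56.9 (8.8) Ω; 78 men / 117 women). The
reference ("DXA") ASM is `truth_model(subject) + N(0, noise_sd)` with the
truth model defaulting to the Sergi coefficient set and noise_sd = 1.2 kg —
on the order of the best published RMSEs, giving a realistic default
scenario. The truth model is explicitly a stand-in for a DXA criterion,
not an estimate of it.

Choices the real cohort does not determine:

* **Correlation structure** is unpublished; defaults are physiologically
  plausible (height–weight +0.4; height–resistance and weight–resistance
  −0.3; resistance–reactance +0.3; age uncorrelated) and fully
  configurable. No claim is made that they match any real cohort.
* **Truncation** uses rejection sampling against per-variable bounds set at
  least ~2.9 SD from every default mean (and inside the record-validation
  ranges), so the induced moment bias is below Monte-Carlo noise at
  n = 10⁴. The age lower bound is 0, so a small tail of generated ages
  falls below typical adult recruitment ages; this is irrelevant to the
  estimator checks the generator exists for.
* **Reference positivity**: the vanishingly rare non-positive reference
  draw is re-drawn rather than clipped, preserving the noise distribution
  conditional on positivity.

What the generator does **not** emulate: measurement drift and device
differences, non-normal or skewed anthropometry, intra-subject repeat
variability, missingness, and any real covariance between impedance and
DXA error. Passing the recovery tests therefore demonstrates that the
estimators recover known generative truth — not that any equation is
accurate in a real population.

`analytic_bias` is the independent oracle for the recovery tests: it
estimates E[equation − truth] under the generative law by Monte Carlo
(default 10⁶ draws) on a seed stream spawned separately from the cohort
stream, so oracle and cohort never share draws. The zero-mean noise term
drops out of the expectation and is not simulated.

## Problem sizes

Default test and acceptance runs use cohorts of 195 (the published cohort's
78/117 sex split), 5,000 for bias recovery (tolerance 3 Monte-Carlo SEs),
10⁴–2·10⁴ for generator moment checks, 10⁵ differences for
limits-of-agreement coverage (tolerance ±0.005 around 0.95), and 10⁶
Monte-Carlo draws for the bias oracle. These sizes put Monte-Carlo noise
well below the assertion tolerances while keeping a full run in seconds.

## Known limitations

* Coefficients are fixed to the published values; no refitting, no new
  equations, no multi-frequency Cole modelling of raw spectra.
* The delta-method RMSE CI is asymptotic; at very small n the bootstrap
  cross-check is the safer read.
* The synthetic default scenario shares its functional family between truth
  model and best-case predictor; equations outside that family (age terms,
  other index conventions) have genuinely nonzero generative bias, which is
  what the recovery tests exploit.
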