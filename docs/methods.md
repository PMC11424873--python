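# Methods

`phytosynergy` analyses a three-herb formulation experiment — *Garcinia
mangostana* (GM), *Curcuma comosa* (CC) and *Acanthus ebracteatus* (AE)
blended at a fixed total mass of 30 g — from extraction optimization
through antioxidant/anti-inflammatory dose-response to synergy and
safety scoring. This note records the models, their assumptions, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Response-surface model

Extraction responses (percent yield; phenolic content, mg gallic-acid
equivalents per g extract; flavonoid content, mg quercetin equivalents
per g extract) are modelled by the full second-order polynomial in the
three herb masses `x = (GM, CC, AE)` in grams:

```
y = b0 + Σ b_i x_i + Σ b_ii x_i² + Σ_{i<j} b_ij x_i x_j + ε,   ε ~ N(0, σ²)
```

fitted by ordinary least squares on the 15-run, three-level Box-Behnken
design (12 edge midpoints, 3 center replicates at 10:10:10 g; levels
5/10/15 g). Ten coefficients against 15 runs leave 5 residual degrees
of freedom, so the two-sided 5% critical value for standardized effects
is `t(0.975, 5) = 2.571`.

Choices:

* **Uncoded coefficients, coded effects.** Coefficients are reported in
  actual gram units, the form in which such polynomials are usually
  printed. Standardized effects `|b|/SE(b)` for the Pareto ranking come
  from the equivalent coded-unit (−1/0/+1) refit: coding puts all
  factors on one scale, which is the convention behind Pareto charts
  and the only parameterization in which per-factor importance is
  comparable. The two fits have identical fitted values, residuals and
  R².
* **R² reported is plain R² × 100** (`rsquared_pct`); adjusted R² is
  computed alongside but not used for comparisons.
* **Optimization is exhaustive grid search** (`grid_optimum`, default
  step 0.5 g, optional fixed-total-mass constraint), deterministic with
  lexicographic (GM, CC, AE) tie-breaking. The search space is tiny, so
  nothing cleverer is warranted. Note that when design runs at a common
  total mass are compared directly, the recommended formulation is the
  best *observed* run (`observed_optimum`); for the bundled data the
  surface argmax and the observed argmax disagree for the yield and
  phenolic responses because the top two candidates sit within a few
  percent of each other on the fitted surface.
* Degenerate inputs: a rank-deficient design raises before fitting; a
  zero-variance response yields NaN R² and an explicit error from the
  standardized-effect ranking.

## Median-effect dose-response model

Inhibition curves follow the mass-action (median-effect) equation
`fa/(1−fa) = (D/Dm)^m`, where `fa` is the fraction affected, `Dm` the
median-effect dose (≡ IC50, µg/mL) and `m` the sigmoidicity. The fit is
unweighted least squares of `log10(fa/(1−fa))` on `log10 D`; the plot's
Pearson `r` measures conformity to the model. Inverse queries use the
closed forms `D(fa) = Dm·(fa/(1−fa))^{1/m}` and
`fa(D) = (D/Dm)^m / (1+(D/Dm)^m)`; IC20 is `D(0.2)`.

Choices:

* Percent inhibition converts as `fa = pct/100`; values are clipped
  into `[0.005, 0.995]` before the logit (per-point flags recorded),
  because the transform diverges at 0 and 1. Clipping never alters
  in-range values. Negative inhibition (pro-oxidant readings) is
  excluded from fits by default.
* Fits use means when replicates are supplied; printed standard
  deviations are carried but not used as weights.
* A non-positive slope raises: inhibition must increase with dose for
  the model to apply.
* `icxx_interpolated` (linear in `fa` vs `log10 D` between bracketing
  observations) is a clearly labelled model-free fallback, used by
  `ic20_from_viability` only when the median-effect plot correlates
  poorly (r < 0.9), with the method recorded in the return value.
* Base-10 logarithms throughout, the median-effect plot convention.

The three-dose (10/20/50 µg/mL) anti-inflammation rows bundled with the
package reproduce their published IC50s to within 15% for nine of ten
rows; the AE-only row cannot be reconciled (fit ≈ 24 vs printed 51
µg/mL) from the printed means alone, and the reproduction report
records it as an advisory failure rather than asserting it.

## Synergy statistics

* **FPI** = combination % inhibition / Σ single-herb % inhibitions at a
  matched concentration. Classification: ≥ 2.0 synergism, [0.5, 2.0)
  additivity, < 0.5 antagonism (the additivity interval is half-open at
  2.0 so the two published rules are disjoint). Classification uses the
  unrounded value; the one-decimal figure (half-up) is reported for
  comparison with published tables.
* **Combination index** for a constant-ratio mixture: with mass
  fractions `w_i`, mixture fit supplying `Dx_mix(fa)` and single-agent
  fits supplying `Dx_i(fa)`,
  `CI(fa) = Σ_i w_i·Dx_mix(fa) / Dx_i(fa)`; CI < 1 synergism, = 1
  additive, > 1 antagonism. The **dose-reduction index**
  `DRI_i = Dx_i/(w_i·Dx_mix)` satisfies `CI = Σ 1/DRI_i` identically;
  components with `w_i = 0` report DRI as undefined (None), not
  infinite. Only constant-ratio designs are supported — the mixtures
  here are dosed by total concentration at fixed mass ratio, so the
  mixture's own median-effect fit is the correct source of `Dx_mix`.
* Reported classification treats `|CI−1| ≤ 1e-9` as additive and a
  configurable band (default ±0.05) as "nearly additive"; the strict
  rule is recovered with a zero band.
* **Isobologram export** returns `(D_i/Dx_i, D_j/Dx_j)` for a component
  pair; the additivity line is `x + y = 1`.

## Safety scoring

Cytotoxicity on L929 fibroblasts is summarized by the IC20 — the dose
at which viability falls to 80%, i.e. `fa = 0.2` with
`fa = (100 − viability)/100`. The selectivity index is
`SI = IC20(cytotoxicity) / IC50(anti-inflammatory activity)`; SI > 1
flags a favorable window. SI is reported raw and, for comparison with
published two-decimal values, rounded half-up. The published IC20
values ship as constants because the viability curves behind them were
not published; `ic20_from_viability` serves user-supplied curves.
`safety_window` intersects the efficacy requirement (inhibition ≥
threshold) with the safety requirement (viability ≥ threshold) using
the two fitted curves' closed-form inverses; an empty window is a valid
result, not an error.

## Synthetic data

The generators produce data with exactly the structure each estimator
assumes, with every stochastic call seeded:

* `gen_bbd_dataset`: responses from a known quadratic surface plus
  i.i.d. Gaussian noise on the 15-run design. Noise is unbounded, so
  synthetic responses may leave physical ranges (e.g. negative yield);
  such runs are constructed without the physical-range validation the
  CSV readers enforce.
* `gen_dose_response`: median-effect curves with Gaussian noise applied
  on the logit-log scale — the scale on which the model is linear — so
  perturbed `fa` stays in (0, 1) without clipping dominating.
* `gen_loewe_mixture`: at each total dose the mixture `fa` solves the
  Loewe additivity equation `Σ_i w_i·D / D_i(fa) = 1` by Brent
  root-finding on (1e-9, 1−1e-9) with 1e-12 dose tolerance. Such
  mixtures have CI = 1 identically, giving a sharp null for the CI
  pipeline (recovered to 1e-6 after refitting the generated curve).

These generators emulate the study's *statistical* structure, not its
chemistry: real extracts have correlated replicate errors, plate
effects, and dose-response shapes that depart from strict mass action.
Passing parameter-recovery and CI = 1 tests therefore validates the
estimators and the synergy algebra, not the biological conclusions
drawn from any particular dataset.

## Problem sizes

All bundled-data computations are closed-form or 15-point least squares
and run in milliseconds. The Monte-Carlo checks use 200 replicate
Box-Behnken simulations (noise SD 2.0, seeds 0–199) for coefficient
unbiasedness and 300 replicate dose-response curves (transformed-scale
noise SD 0.05, seeds 0–299) for median-Dm recovery — sizes chosen so
sampling error is well below the tested tolerances.

## Known limitations

* IC50s are point estimates; no confidence intervals are propagated
  from replicate standard deviations.
* Only three-factor designs are handled by the response-surface layer,
  and only constant-ratio mixtures by the CI layer.
* The FPI thresholds and CI classification are the conventional rules;
  no multiple-testing or uncertainty treatment is applied to
  classifications near the boundaries.
* Standard curves are fitted unweighted on the raw concentration
  scale; heteroscedastic absorbance noise is not modelled.
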