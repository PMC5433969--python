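# Methods

`cetcond` implements a body-condition evaluation chain for small cetaceans
(developed around stranded harbor porpoises) in three layers: morphometric
condition indices with their allometric underpinnings, a ground-truthing
framework that ranks those indices, and a blubber-cortisol
quantification-and-modelling chain. Because strandings morphometrics and
assay plate files are rarely shareable, the package ships a calibrated
synthetic generator so every stage can be exercised end to end.

## Condition indices and allometry

Ten indices are computed per animal (units: mass kg, length/girth cm,
blubber mm): ventral blubber depth, blubber/girth, blubber/length,
girth/length, mass/length, Fulton's K = M/L³, Quetelet's index (BMI)
= M/L², relative condition Kn = M/M*, the residual index R (residuals of
ln M on ln L), and the scaled mass index M̂ = M·(L₀/L)^b_SMA.

Three fits support them:

* **Log-log OLS** of ln M on ln L. Its residuals are the residual index
  (they sum to zero by the normal equations), and its back-transform
  a·L^b is the predicting curve for Kn, so the geometric mean of Kn over
  the fitting set is exactly 1. Fitting Kn's curve on the log scale is a
  deliberate choice (consistent with the residual index and standard
  usage); the nonlinear power fit is available separately if a direct
  absolute-scale curve is wanted.
* **SMA regression**: b_SMA = b_OLS / r, equivalently sign(r)·sd(lnM)/sd(lnL).
  L₀ defaults to the arithmetic mean length of the records supplied and can
  be overridden for cross-dataset comparability.
* **Nonlinear least squares** for M = δ + α·L^β (scipy `curve_fit`),
  started deterministically from the log-log fit (δ=0, α=exp(intercept),
  β=slope) with tight tolerances; confidence intervals are asymptotic
  (Wald, t reference with n−3 df). A seeded bootstrap is easy to add but
  was not needed: Wald intervals cover a true intercept ≥90% of the time
  in the additive-noise simulation the tests run.

The size-independence diagnostic is the Pearson correlation of an index
with length. When β is far from 1, M/L correlates strongly with length and
a power ratio M/L^k with k ≈ β is the size-free choice — this is what
redirects the recommendation from mass/length to mass/length².

## Ground-truthing framework

Each index is regressed (OLS, treatment coding with references acute /
adult / nonbreeding so hypothesized deficits appear as negative
coefficients) on cause-of-death class, age class, season, and
age-class:season. All marginality-respecting subsets are fitted and ranked
by AIC (AICc for the small cortisol models); Akaike weights are
exp(−Δ/2) normalized; two leading models within Δ<2 are flagged
equivalent. "Backwards selection with dredge" is exhaustive enumeration,
which is what dredge actually does.

Three directional expectations give the verdicts: chronic < acute
condition, adults highest among age classes, breeding-season deficit. A
term dropped by selection is 'n/a'; retained with the expected sign '+';
retained contrary '−'. Partial η² = SS_term/(SS_term+SS_error) uses Type
II sums of squares via nested model comparison (matching the conventional
linear-model default; verified against statsmodels `anova_lm(typ=2)`).

Ranking: discard indices with a '−' age-class verdict or an empty best
model; take the survivor with the highest adjusted R² as provisional
winner; if mass/length visibly tracks length (|r| > 0.3, a conservative
threshold for "visibly correlated") and the provisional winner belongs to
the M/L^k family, recommend the surviving family member with k nearest
the fitted β. Every decision is written to an audit trail.

Levene's homogeneity test uses deviations from the group mean by default
(the classical Levene form; the median-centred Brown-Forsythe variant is
available). The degenerate case where all deviations are equal returns
W=0, p=1.

## Cortisol chain

Quantification follows the competitive-ELISA geometry: response
y(x) = d + (a−d)/(1+(x/c)^b) with a > d, fitted per plate to ≥5 standards
(0–800 ng/ml including zero), inverted in closed form
x = c·((a−y)/(y−d))^(1/b). Inverted values below the 2.5 ng/ml
sensitivity are flagged below-LOD, never imputed. Duplicates are averaged
after inversion. Tissue concentration is
ng/g = ng/ml × 0.5 ml / tissue mass / extraction efficiency, with
efficiency supplied per sample (default 1). QC gates: mean duplicate CV
< 10% (intra-assay), mean across-plate control CV < 20% (inter-assay).

Concentrations are modelled with gamma log-link models. Site and layer
models add a Gaussian random intercept per individual (repeated
measures); the estimator is Laplace-approximated maximum likelihood
written for this package (statsmodels has no gamma mixed model): the
conditional mode per individual is found by a vectorized 1-D Newton
iteration (the conditional log-posterior is strictly concave), and the
outer problem optimizes (β, log σ_u, log shape) by L-BFGS-B, with SEs
from the finite-difference Hessian. The implementation reproduces
glmmTMB's Gamma/Laplace fits to ≈1e-5 on a fixed test dataset. With
σ_u ≈ 0 it collapses to the fixed-effects GLM. Fixed-effects gamma GLMs
(the covariate analysis) use statsmodels IRLS with the shape estimated by
maximum likelihood so AICc is comparable across candidates
(k = p + 1 (+1 for σ_u in mixed fits)). Population-averaged means
back-transform with the lognormal correction exp(σ_u²/2).

## Synthetic generator

The generator's defaults are the study conditions:

* **Morphometrics** (default n=291, males): age mix calf/juvenile/adult =
  0.10/0.45/0.45 (strandings-realistic; only the cutoffs are published);
  lengths from truncated normals 75±8 on [60,90] (calf) and 145±8 on
  [135,175] (adult), uniform 90–135 for juveniles. Baseline mass
  δ + α·L^β with δ=−3.17, α=4e−4, β=2.33. Cause of death per age class
  (acute probability 0.25/0.478/0.491) and a per-group condition
  multiplier calibrated in-sample so acute/chronic mean M/L² hit
  0.0022/0.0018 kg/cm²; individual condition noise is added only up to
  the target total group SDs (0.00035/0.00050) so the structural
  cross-age spread is not double-counted. Residual log-normal mass noise
  sd 0.05. Girth ≈ 0.55·L·c^0.5, blubber ≈ (0.095–0.105)·L·c, giving the
  qualitative verdict pattern of the real data (blubber ratios and
  Fulton's K fail the age-class expectation; the power ratios pass).
  Season effect defaults to 0 (never retained in the source analysis).
* **Cortisol field**: log-mean = stratum baseline + age shift
  (juvenile +0.45) + condition slope (−250 per kg/cm², i.e. ≈ −0.1 per
  within-group SD of M/L²) + individual intercept (σ_u=0.4), gamma noise
  on the response scale. Stratum baselines are the printed full-depth
  site means (69.09/90.48/83.22 ng/g); layer multipliers are the printed
  layer means relative to the mean site level (80.93 ng/g) with
  full-depth fixed at 1 — the source's own full-depth figures differ
  between its two subsets (80.93 vs 88.65), and this anchoring satisfies
  both within 10%. The covariate (outer-dorsal, one sample per animal)
  design uses the printed sex means (111.37/66.77) as sex-specific
  baselines. Deviations are recentred within each calibration stratum on
  the response scale, so configured means are hit in expectation
  regardless of the other effects. Gamma shape 2.5 for repeated-measures
  designs (stratum CVs ≈ 0.8, inside the printed 0.45–1.0 span) and 15
  for the covariate design (total CV ≈ 0.5, matching the printed
  sex-group SDs); a single shape cannot satisfy both printed dispersion
  regimes.
* **Assay plates**: 4PL (a=2.0, d=0.1, c=100, b=1.2), standards
  0/2.5/10/30/100/300/800 ng/ml. Noise acts multiplicatively on the
  effective analyte concentration of sample wells (pipetting/extraction
  error), never on standards, so inversion stays in range and duplicate
  CVs live on the reported concentration scale. The per-well log-sd is
  the 5.65% intra-assay target divided by c4(2)=√(2/π), because the mean
  duplicate-pair CV underestimates the underlying sd; the plate-level
  shift supplies the 10.84% inter-assay target. The mass→efficiency
  curve rises to a plateau over 0.15–0.2 g and declines beyond it (an
  assumption; the source recommends that mass window without printing
  the curve).

What the generator does **not** emulate: measurement error in length or
girth, carcass decomposition, spatial/temporal stranding structure,
progesterone cross-reactivity (available as an optional additive bias,
default 0), or any correlation between an individual's morphometric and
cortisol records (the subsets are drawn independently). Passing tests
therefore demonstrate that the estimators recover the structure this
model encodes at the stated sample sizes — not that real strandings data
meet these assumptions.

## Numerical choices and degenerate inputs

* NLS and 4PL fits run with tolerances near machine precision so
  noise-free round trips are exact to ~1e−12; non-convergence is flagged
  (`converged=False` / error), never silently accepted.
* Records missing a field are excluded per index with a logged count;
  malformed CSV rows are rejected individually and reported.
* Zero-variance vectors raise explicit undefined-correlation /
  singular-fit errors; factor columns with a single observed level are
  dropped from the candidate set before selection.
* Candidate models that fail to fit are excluded from the Akaike weights
  and logged; the weights are renormalized over the fitted set.
* Below-LOD concentrations are retained with a flag.
* Selection is deterministic and invariant to candidate order (subsets
  are enumerated in sorted order; ties broken by model size).

## Problem sizes used by the shipped checks

The acceptance script regenerates everything from scratch per run: 20
replicates of n=291 for the allometric exponent (median reported), 2000
individuals for the cortisol field recoveries, and 200 plates × 10
duplicate samples for the CV recovery. The test suite uses the same
scales, plus 1000-replicate type-I calibration for Levene's test and a
100-replicate 2-SE coverage check for the mixed model at 500 individuals.

## Known limitations

* The Laplace approximation can bias variance components slightly for
  very small groups (n=6 layer design); the contract is sign/recovery
  fidelity, which the tests verify, not exact variance estimation.
* Partial η² values and adjusted R² of the original analyses are not
  reproducible without the undeposited raw data; the framework reports
  its own values and the tests assert identities and oracles, not the
  published effect sizes.
* The evaluation stage assumes Gaussian index residuals (as the original
  linear models do); heavy-tailed indices would need a robust variant.
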