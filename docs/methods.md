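# Methods

This note records the statistical models the package implements, the choices
made where conventions diverge, and what the synthetic-data tests do and do
not establish about real survey data.

## Data model

The universal container is a tidy person-level table: sex, age, waist
circumference (cm, possibly missing), a continuous wealth score (higher =
wealthier; typically a principal-components asset index built upstream by the
survey agency), an expansion-factor weight, optional PSU/stratum identifiers,
and ordered-categorical covariates. Hard invariants (positive weight, finite
wealth, positive waist where present, unique person id within year) are
enforced at construction; ingestion drops and counts violating rows rather
than failing.

Eligibility filtering reproduces the usual adult-anthropometry inclusion
rules: age ≥ 18, a waist measurement present, not pregnant. Counts are
reported per reason in a fixed order (age, pregnancy, missing waist), each
record counted once under the first rule it fails.

### Pooling survey years

When two annual waves are pooled the combination of their expansion factors
is a genuine modelling choice: summed as-is, the wave with the larger
expansion totals dominates weighted estimates. The default
(`per_year_normalized`) rescales each year's weights so its weight total
equals its unweighted sample size — each wave then contributes in proportion
to the information it carries. `as_is` is available for users whose weights
are already harmonized.

### Wealth quintiles

Quintile boundaries sit at cumulative weight fractions 0.2/0.4/0.6/0.8 of
the wealth-sorted population. Tied wealth scores form one group and share a
quintile. A group straddling a cut is assigned to the quintile containing
the midpoint of its cumulative-weight interval, with a midpoint exactly on a
cut going to the lower quintile — a fixed, documented convention; under
continuous wealth each quintile's weighted share is within one percentage
point of 20%. Because the rule is rank-based, assignments are invariant to
strictly monotone re-expressions of the wealth score.

## Descriptives

AO classification applies the sex-specific comparator exactly: IDF is
inclusive (≥ 90 / ≥ 80 cm), ATP III strict (> 102 / > 88 cm), LASO inclusive
(≥ 97 / ≥ 94 cm). Missing waist yields a missing outcome marker, never a
silent negative.

Weighted prevalences are ratio estimators Σwy/Σw. Their uncertainty uses,
by default, whichever method the data support: Taylor-linearized variance
with PSUs as first-stage clusters within strata (with-replacement
approximation) when design columns are complete, otherwise a Wilson interval
on the Kish effective sample size (Σw)²/Σw². Cells with zero outcome
variance get the degenerate interval [p, p]. Weighted means use the same
machinery; a single-record cell reports an undefined SE.

Direct age-standardization is the standard-weighted average of band
prevalences. The WHO 2001 world-standard weights (18 five-year bands) are
embedded; because the conventional printed percents sum to 100.03, they are
normalized at construction. For adult analyses the bands are collapsed onto
18–29 / 30–59 / 60+, splitting the 15–19 band uniformly by year of age (2/5
of its weight to 18–29) and renormalizing — an explicit approximation, since
five-year bands do not align with an 18+ cut.

## Concentration indices

Ranks are Lerman–Yitzhaki weighted fractional ranks with shared mid-ranks
for ties, which keeps the weighted mean rank at exactly ½. CI is computed
from the weighted covariance; the Erreygers correction multiplies by
4μ/(b−a) with bounds (0,1) for binary outcomes. Degenerate cases are
explicit: μ = 0 raises (the index is undefined), a constant outcome returns
an exact 0 (flagged degenerate when binary), coincident bounds raise.

Standard errors come from the convenient regression — the WLS fit of
`2σ²_R y/μ` (or `8σ²_R y/(b−a)` on the ECI scale) on the rank, whose slope
equals the index — with HC1 robust covariance, or PSU-clustered covariance
when requested and available. The SE estimator behind published index SEs is
rarely stated; the convenient-regression form is the standard practice in
the concentration-index literature and is validated here against a
nonparametric bootstrap (agreement within 10% at n = 5,000).

Subgroup indices (e.g. per sex) re-rank within the subgroup by default:
sex-specific indices answer "how is the outcome distributed across the
wealth distribution *of that sex*", which is the defensible reading when
results are reported separately by sex. Ranking on the pooled sample is
available (`rank_scope: pooled`).

The concentration curve is the record-level cumulation of weight vs weighted
outcome share in wealth order; with distinct wealth values the trapezoidal
area satisfies CI = 1 − 2·AUC to machine precision, which the tests exploit
as a consistency check.

## Decomposition

A weighted binomial GLM (logit link; identity link behind a flag for
sensitivity) is fitted to the outcome on dummy-coded covariates against
declared reference levels. Partial effects are marginal effects **at the
sample means**, `β_k p̄(1−p̄)` with `p̄` the fitted probability at the
weighted mean design vector — not average marginal effects; the choice
matters only at second order but is fixed and documented. Quasi-separation
is detected (|coefficient| > 25 on the logit scale) and raised as an
estimation error naming the term.

The Erreygers scaling factor 4 is folded into the elasticity column,
`elasticity_k = 4 β_k^m x̄_k`, so that the printed-table identity
`contribution = elasticity × CI_k` holds row by row and rows plus residual
sum to the total ECI. `CI_k` is the plain (uncorrected) concentration index
of the dummy over the same ranks — the Erreygers correction applies to the
bounded outcome, not to the regressors. The residual is defined by closure
(total − Σ contributions) and cross-checked against 4× the generalized CI of
the GLM error term; both are reported. The residual is small (percent-level)
only when the covariates span the wealth gradient — e.g. when the wealth
quintile dummies are included, as the full pipeline does; with a direct
wealth→outcome path omitted from the covariate set, the residual correctly
absorbs it.

## Synthetic survey generator

The generator emulates the structure of a two-stage national health survey:

* wealth score standard normal (lognormal/uniform re-expressions available —
  all structural models consume the *population fractional rank*, the CDF
  value, so the concentration structure is invariant to the score's shape);
* expansion factors gamma(4, 0.25) (mean 1, coefficient of variation ½ —
  mild, realistic dispersion), constant weights for oracle checks, or a
  `design` mode that assigns strata/PSUs and adds a PSU-level logistic
  random intercept with variance ρ/(1−ρ)·π²/3 for a target latent
  intra-cluster correlation ρ;
* eight ordered categorical covariates (age group, marital status,
  education, natural region, urban/rural, altitude band, chronic disease,
  smoking) drawn from proportional-odds models on the centred wealth rank —
  one log-odds slope per covariate controls its socioeconomic sorting, with
  marginal probabilities at median wealth matching published adult-survey
  descriptives;
* a binary outcome from a logistic model (per-sex intercepts, slope on the
  wealth rank, per-category coefficients), and a waist-circumference model
  (per-sex base + gradient × rank + Gaussian noise) whose defaults mirror
  published sex-specific means (≈93.5 cm men, ≈92.3 cm women) and quintile
  gradients (men ≈ 11 cm across quintiles, women ≈ 4 cm and flat);
* one global seed feeding named, CRC-keyed sub-streams per component, so
  adding a covariate never perturbs wealth, weights, sex or earlier draws —
  the determinism and isolation are unit-tested.

Two oracles anchor recovery tests. `true_eci_by_simulation` runs the
estimator on a 10⁶-record population from the same design.
`design_for_target_eci` inverts the covariate-free model analytically:
μ = ∫ expit(a+br) dr and ECI = 8 ∫ expit(a+br)(r−½) dr are solved for (a, b)
by quadrature plus root-finding, so designs with population ECI of exactly
0, 0.1 or 0.35 are constructed, not tuned.

**What passing tests show — and don't.** The synthetic data are
logistic-family, independently sampled, with weights independent of the
outcome and no nonresponse, calibration weighting, or measurement error in
waist circumference. Recovery results therefore validate the estimators and
the arithmetic, not the design-based variance under a real two-stage sample,
and say nothing about cut-off validity in any specific population.

## Problem sizes and numerical choices

Monte-Carlo checks use n = 50,000 samples against 10⁶-record oracles (100
replicates) for index recovery, and n = 20,000 (100 replicates) for
decomposition recovery — sizes at which sampling noise is comfortably below
the effects being detected while the full suite runs in about a minute.
Tolerances follow the quantity's nature: algebraic identities at 1e-10 to
1e-12, the curve–index identity at 1e-6 (trapezoid on the record-level
curve), Monte-Carlo assertions at 3–4 standard errors. Floating-point ties
at quintile cuts are resolved with a 1e-12 guard toward the lower quintile.

## Known limitations

* The Taylor variance ignores finite-population corrections and second-stage
  variance (standard with-replacement shortcut).
* Marginal effects at means are reported without delta-method variance for
  the mean point itself (the GLM coefficient SE is scaled instead).
* The `.sav` (SPSS) reader is not included; data arrive as delimited text
  with a column-role mapping.
* Dominance tests between concentration curves, generalized/Wagstaff
  indices, and decompositions of between-group index differences are out of
  scope.
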