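# ineqdecomp

Survey-weighted measurement and decomposition of socioeconomic inequality in
binary health outcomes, built around the motivating case of abdominal obesity
(AO) in adult health-survey data ranked by a household wealth index.

## Who this is for

Epidemiologists and health economists working with complex-survey microdata
(one row per respondent, expansion-factor weights, optional PSU/stratum
design columns) who want, in one reproducible pipeline:

* AO classification under the standard waist-circumference cut-offs
  (IDF ≥90/≥80 cm, ATP III >102/>88 cm, LASO ≥97/≥94 cm for men/women);
* survey-weighted prevalences and means with design-based confidence
  intervals, and WHO direct age-standardization;
* wealth-ranked concentration curves and the concentration index with the
  Erreygers correction for binary outcomes;
* a regression-based decomposition of that inequality into covariate
  contributions;
* a synthetic complex-survey generator with a *known* gradient, so the whole
  chain is testable without any restricted data.

## The statistics

With weighted fractional ranks `R_i` (Lerman–Yitzhaki: cumulative normalized
weight of all strictly poorer respondents plus half one's own tied group;
weighted mean exactly ½) the concentration index of outcome `y` with weighted
mean `μ` is

```
CI = (2 / μ) · cov_w(y, R)
```

For a binary outcome the attainable range of CI shrinks as `μ` grows, so the
Erreygers correction is used:

```
ECI = 4 μ (b − a)⁻¹ · CI   =   4 μ · CI   for y ∈ {0, 1}
```

`ECI > 0` means the outcome is concentrated among the wealthier (pro-rich
inequality). Standard errors come from the convenient WLS regression whose
slope equals the index, with heteroskedasticity-robust or PSU-cluster-robust
covariance.

The decomposition fits a weighted binomial GLM (logit link) of `y` on
dummy-coded covariates and evaluates marginal effects at the sample means
(`β_k · p̄(1 − p̄)`). Each dummy contributes

```
contribution_k = [4 · β_k^m · x̄_k] · CI_k
```

where `CI_k` is the dummy's own concentration index over the same ranks; the
bracket is reported as the elasticity column, so rows satisfy
`contribution = elasticity × CI_k` and, with the residual (the scaled
generalized CI of the model error), sum exactly to the total ECI.

## Worked example

```python
from ineqdecomp import (default_design, generate_population,
                        classify_abdominal_obesity, RankedOutcome,
                        erreygers_index, decompose_eci)

survey = generate_population(default_design(n=20_000, seed=7))
for sex in ("male", "female"):
    sub = survey.subset((survey.frame["sex"] == sex).to_numpy())
    g = sub.frame
    ao = classify_abdominal_obesity(g["waist_cm"].to_numpy(),
                                    g["sex"].to_numpy(), "IDF")
    ranked = RankedOutcome.from_arrays(ao, g["wealth_score"].to_numpy(),
                                       g["weight"].to_numpy())
    eci = erreygers_index(ranked)
    print(f"{sex}: prevalence {100*ranked.mu:.1f}%  "
          f"ECI {eci.value:.3f} (SE {eci.se:.4f})")
```

prints

```
male: prevalence 62.4%  ECI 0.324 (SE 0.0124)
female: prevalence 86.2%  ECI 0.052 (SE 0.0084)
```

i.e. in this generated survey AO is markedly pro-rich among men (ECI 0.32)
and only mildly so among women, whose prevalence is already high across the
wealth distribution. Decomposing the men's index over a few covariates:

```python
sub = survey.subset((survey.frame["sex"] == "male").to_numpy())
g = sub.frame.copy()
g["ao"] = classify_abdominal_obesity(g["waist_cm"].to_numpy(),
                                     g["sex"].to_numpy(), "IDF")
result = decompose_eci(sub.replace_frame(g), "ao",
                       ["education", "area", "chronic_disease"])
print(result.to_frame().round(3).to_string(index=False))
```

```
       variable     level  elasticity   ci_k  contribution    pct
      education   primary       0.042 -0.249        -0.010 -3.209
      education secondary       0.122 -0.056        -0.007 -2.114
      education    higher       0.215  0.256         0.055 17.007
           area     urban       0.214  0.106         0.023  6.978
chronic_disease       yes       0.012  0.040         0.000  0.143
```

Higher education is both pro-rich (`ci_k = 0.256`) and positively associated
with AO, so it pushes inequality up (17% of the total); the large residual
here reflects the direct wealth gradient these three covariates do not span
(adding the wealth-quintile dummies, as the full pipeline does, absorbs it).

## Command line

```
ineqdecomp synth --n 10000 --seed 1 --out survey.csv
ineqdecomp concindex --input survey.csv --outcome outcome --by sex --index eci
ineqdecomp decompose --input survey.csv --outcome outcome \
    --covariates education,area --by sex
ineqdecomp run --config run.yaml
```

`run` executes the full pipeline (eligibility → pooling → quintiles →
descriptives → curves → indices → decomposition) and writes a fixed set of
CSVs plus a `manifest.json` with the config hash and exclusion counts.
Exit codes: 0 ok, 2 configuration error, 3 data error, 4 estimation error.

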