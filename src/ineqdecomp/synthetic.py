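"""Synthetic complex-survey microdata with a known socioeconomic gradient.

The generator emulates the structure of a national demographic health survey
(one adult per row: sex, age, waist circumference, a continuous household
wealth score, an expansion-factor weight, and categorical sociodemographic
covariates correlated with wealth).  Its purpose is to make every downstream
stage — prevalence, concentration curves, Erreygers index, decomposition —
testable end-to-end with a controllable ground truth.

Design principles
-----------------
* Wealth enters every structural model through its *population fractional
  rank* (the CDF of the wealth distribution), never the raw score.  The true
  concentration structure is therefore invariant to monotone re-expressions
  of wealth, matching the rank-based estimand.
* Categorical covariates follow proportional-odds models on the centred
  wealth rank; a single log-odds slope per covariate controls how strongly
  its categories sort along the wealth axis.
* The binary outcome follows a logistic model with per-sex intercepts, a
  slope on the wealth rank, and per-category coefficients.
* One global seed feeds named sub-streams (wealth, weights, each covariate,
  outcome, waist ...), so adding or removing one component never perturbs the
  draws of another.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import expit, logit

from .inequality import RankedOutcome, erreygers_index, fractional_rank
from .survey_data import CORE_COLUMNS, ConfigurationError, SurveyDataset

__all__ = [
    "CategoricalSpec",
    "WeightSpec",
    "WaistSpec",
    "OutcomeSpec",
    "SyntheticDesign",
    "default_design",
    "rank_only_design",
    "design_for_target_eci",
    "generate_population",
    "true_eci_by_simulation",
    "analytic_outcome_mean",
    "analytic_eci",
]


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalSpec:
    """One covariate: ordered levels, marginal probabilities at median wealth,
    a proportional-odds log-slope on the centred wealth rank (positive pushes
    richer respondents toward higher levels), and per-level outcome log-odds
    coefficients (first level is the reference and must carry 0)."""

    name: str
    levels: tuple[str, ...]
    base_probs: tuple[float, ...]
    rank_slope: float = 0.0
    outcome_coefs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probs, dtype=float)
        if len(p) != len(self.levels) or len(self.levels) < 2:
            raise ConfigurationError(f"{self.name}: levels/base_probs mismatch")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.name}: base_probs must sum to 1")
        coefs = self.outcome_coefs or tuple(0.0 for _ in self.levels)
        if len(coefs) != len(self.levels):
            raise ConfigurationError(f"{self.name}: outcome_coefs mismatch")
        if coefs[0] != 0.0:
            raise ConfigurationError(f"{self.name}: reference level must have coef 0")
        object.__setattr__(self, "outcome_coefs", tuple(coefs))


@dataclass(frozen=True)
class WeightSpec:
    """Expansion-factor model: 'constant' (all 1) or 'gamma' dispersion with
    mean shape*scale, or 'design' which additionally assigns strata and PSUs
    and induces within-PSU outcome correlation via a latent logistic random
    intercept."""

    kind: str = "gamma"
    shape: float = 4.0
    scale: float = 0.25
    strata: int = 8
    psu_per_stratum: int = 12
    within_psu_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gamma", "design"):
            raise ConfigurationError(f"unknown weight model {self.kind!r}")
        if self.kind != "constant" and (self.shape <= 0 or self.scale <= 0):
            raise ConfigurationError("gamma weight parameters must be positive")
        if not 0.0 <= self.within_psu_correlation < 1.0:
            raise ConfigurationError("within_psu_correlation must be in [0, 1)")


@dataclass(frozen=True)
class WaistSpec:
    """Continuous waist generator: per-sex base + gradient * wealth rank +
    Gaussian noise (centimetres)."""

    male_base: float = 86.5
    male_gradient: float = 13.9
    female_base: float = 89.8
    female_gradient: float = 5.0
    sd_male: float = 10.5
    sd_female: float = 11.0


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary-outcome logistic model: per-sex intercepts and a log-odds slope
    on the (uncentred) wealth rank."""

    intercept_male: float = 0.0
    intercept_female: float = 0.0
    rank_slope: float = 0.0


@dataclass(frozen=True)
class SyntheticDesign:
    """Complete parameterization of the generator; identical (design, seed)
    pairs produce bit-identical datasets."""

    n: int
    seed: int
    sex_split: float = 0.569          # proportion female
    wealth_dist: str = "normal"       # normal | lognormal | uniform
    weight_model: WeightSpec = WeightSpec()
    covariates: tuple[CategoricalSpec, ...] = ()
    outcome_model: OutcomeSpec = OutcomeSpec()
    waist_model: Optional[WaistSpec] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        if not 0.0 < self.sex_split < 1.0:
            raise ConfigurationError("sex_split must be in (0, 1)")
        if self.wealth_dist not in ("normal", "lognormal", "uniform"):
            raise ConfigurationError(f"unknown wealth_dist {self.wealth_dist!r}")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream: a generator keyed by (seed, crc32(stream))."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _wealth_and_rank(design: SyntheticDesign) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(design.seed, "wealth")
    z = rng.standard_normal(design.n)
    r = stats.norm.cdf(z)  # population fractional rank
    if design.wealth_dist == "normal":
        score = z
    elif design.wealth_dist == "lognormal":
        score = np.exp(z)
    else:
        score = r
    return score, r


def _draw_categorical(spec: CategoricalSpec, r: np.ndarray, seed: int) -> np.ndarray:
    """Proportional-odds draw: cumulative logits shifted by -slope*(r-1/2)."""
    cum = np.cumsum(spec.base_probs)[:-1]
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    c = logit(cum)
    # rows: records; cols: cumulative cutpoints
    cum_r = expit(c[None, :] - spec.rank_slope * (r[:, None] - 0.5))
    u = _rng(seed, f"cov:{spec.name}").random(len(r))
    codes = np.sum(u[:, None] > cum_r, axis=1)
    return codes


def generate_population(design: SyntheticDesign) -> SurveyDataset:
    """Generate ``design.n`` survey records as a :class:`SurveyDataset`.

    The frame carries the canonical core columns, one ordered-categorical
    column per covariate, and a binary ``outcome`` column; ``waist_cm`` is
    populated when the design has a waist model (NaN otherwise).
    """
    n, seed = design.n, design.seed
    score, r = _wealth_and_rank(design)

    female = _rng(seed, "sex").random(n) < design.sex_split
    sex = np.where(female, "female", "male")

    wm = design.weight_model
    if wm.kind == "constant":
        w = np.ones(n)
    else:
        w = _rng(seed, "weights").gamma(wm.shape, wm.scale, size=n)
    psu = np.full(n, pd.NA, dtype=object)
    stratum = np.full(n, pd.NA, dtype=object)
    psu_effect = np.zeros(n)
    if wm.kind == "design":
        rng_d = _rng(seed, "design")
        stratum_id = rng_d.integers(0, wm.strata, size=n)
        psu_id = rng_d.integers(0, wm.psu_per_stratum, size=n)
        stratum = np.array([f"s{s}" for s in stratum_id], dtype=object)
        psu = np.array([f"s{s}p{p}" for s, p in zip(stratum_id, psu_id)], dtype=object)
        rho = wm.within_psu_correlation
        if rho > 0:
            sigma = np.sqrt(rho / (1 - rho) * np.pi ** 2 / 3.0)
            effects = rng_d.normal(0.0, sigma, size=(wm.strata, wm.psu_per_stratum))
            psu_effect = effects[stratum_id, psu_id]

    frame = pd.DataFrame({
        "person_id": np.arange(n).astype(str),
        "year": "synthetic",
        "sex": sex,
        "waist_cm": np.nan,
        "wealth_score": score,
        "weight": w,
        "psu": psu,
        "stratum": stratum,
        "pregnant": False,
    })

    lin = np.where(
        female, design.outcome_model.intercept_female, design.outcome_model.intercept_male
    ) + design.outcome_model.rank_slope * r + psu_effect

    covs = {}
    age_years = None
    for spec in design.covariates:
        codes = _draw_categorical(spec, r, seed)
        lin = lin + np.asarray(spec.outcome_coefs)[codes]
        frame[spec.name] = pd.Categorical.from_codes(
            codes, categories=list(spec.levels), ordered=True
        )
        covs[spec.name] = list(spec.levels)
        if spec.name == "age_group":
            # continuous age uniform within the drawn band
            u = _rng(seed, "age_years").random(n)
            lo = np.array([18.0, 30.0, 60.0])[codes]
            hi = np.array([30.0, 60.0, 90.0])[codes]
            age_years = np.floor(lo + u * (hi - lo))
    frame["age_years"] = age_years if age_years is not None else 40.0

    p = expit(lin)
    frame["outcome"] = (_rng(seed, "outcome").random(n) < p).astype(float)

    if design.waist_model is not None:
        ws = design.waist_model
        base = np.where(female, ws.female_base, ws.male_base)
        grad = np.where(female, ws.female_gradient, ws.male_gradient)
        sd = np.where(female, ws.sd_female, ws.sd_male)
        frame["waist_cm"] = base + grad * r + sd * _rng(seed, "waist").standard_normal(n)

    order = list(CORE_COLUMNS) + list(covs) + ["outcome"]
    return SurveyDataset(frame[order], covs)


# ---------------------------------------------------------------------------
# Ground-truth oracles
# ---------------------------------------------------------------------------

def true_eci_by_simulation(
    design: SyntheticDesign, n_oracle: int = 1_000_000, seed: int | None = None
) -> float:
    """Oracle Erreygers index: generate one very large population from the
    design and run the estimator on it.  Serves as ground truth for
    parameter-recovery tests."""
    oracle_seed = (design.seed ^ 0x5EED) & 0x7FFFFFFF if seed is None else seed
    big = dataclasses.replace(design, n=n_oracle, seed=oracle_seed)
    d = generate_population(big)
    f = d.frame
    ranked = RankedOutcome.from_arrays(
        f["outcome"].to_numpy(), f["wealth_score"].to_numpy(), f["weight"].to_numpy()
    )
    return erreygers_index(ranked, compute_se=False).value


def analytic_outcome_mean(a: float, b: float) -> float:
    """Mean of expit(a + b*r) over r ~ U(0,1) (covariate-free designs)."""
    val, _ = integrate.quad(lambda r: expit(a + b * r), 0.0, 1.0, limit=200)
    return val


def analytic_eci(a: float, b: float) -> float:
    """Erreygers index implied by the rank-only model p(r) = expit(a + b*r):
    ECI = 8 * integral of p(r) * (r - 1/2) dr."""
    val, _ = integrate.quad(lambda r: expit(a + b * r) * (r - 0.5), 0.0, 1.0, limit=200)
    return 8.0 * val


def design_for_target_eci(
    target_eci: float,
    mu: float,
    n: int,
    seed: int,
    *,
    weight_model: WeightSpec = WeightSpec(),
) -> SyntheticDesign:
    """Covariate-free design whose population ECI and prevalence equal the
    requested values, obtained by solving the rank-logistic moments
    (deterministic quadrature + root finding)."""
    if not 0.0 < mu < 1.0:
        raise ConfigurationError("mu must be in (0, 1)")

    if target_eci == 0.0:
        a, b = float(logit(mu)), 0.0
    else:
        def equations(v):
            a, b = v
            return (analytic_outcome_mean(a, b) - mu, analytic_eci(a, b) - target_eci)

        (a, b), info, ier, msg = optimize.fsolve(
            equations, x0=(logit(mu), 4.0 * target_eci), full_output=True
        )
        if ier != 1:
            raise ConfigurationError(f"could not calibrate design: {msg}")
    return SyntheticDesign(
        n=n, seed=seed, sex_split=0.5, weight_model=weight_model,
        outcome_model=OutcomeSpec(intercept_male=a, intercept_female=a, rank_slope=b),
    )


def rank_only_design(n: int, seed: int, a: float, b: float,
                     weight_model: WeightSpec = WeightSpec()) -> SyntheticDesign:
    """Covariate-free design with explicit logistic coefficients."""
    return SyntheticDesign(
        n=n, seed=seed, sex_split=0.5, weight_model=weight_model,
        outcome_model=OutcomeSpec(intercept_male=a, intercept_female=a, rank_slope=b),
    )


# ---------------------------------------------------------------------------
# Default survey-like design
# ---------------------------------------------------------------------------

def default_design(n: int = 62138, seed: int = 0) -> SyntheticDesign:
    """Survey-like default: eight sociodemographic covariates with marginals
    and wealth gradients typical of a Peruvian adult health survey, a
    waist-circumference model whose sex-specific means and wealth gradients
    mirror published descriptives (men steeper than women), and gamma(4, .25)
    expansion-factor dispersion.
    """
    covariates = (
        CategoricalSpec("age_group", ("18-29", "30-59", "60+"),
                        (0.272, 0.546, 0.182), rank_slope=0.15,
                        outcome_coefs=(0.0, 1.3, 1.4)),
        CategoricalSpec("marital_status",
                        ("never_married", "married_cohabiting", "separated_widowed"),
                        (0.172, 0.661, 0.167), rank_slope=-0.2,
                        outcome_coefs=(0.0, 0.8, 0.7)),
        CategoricalSpec("education", ("none", "primary", "secondary", "higher"),
                        (0.04, 0.206, 0.401, 0.353), rank_slope=2.4,
                        outcome_coefs=(0.0, 0.15, 0.25, 0.45)),
        CategoricalSpec("region",
                        ("jungle", "mountain", "rest_coast", "lima"),
                        (0.121, 0.249, 0.257, 0.373), rank_slope=1.6,
                        outcome_coefs=(0.0, -0.2, 0.35, 0.4)),
        CategoricalSpec("area", ("rural", "urban"), (0.194, 0.806),
                        rank_slope=3.0, outcome_coefs=(0.0, 0.5)),
        CategoricalSpec("altitude", ("0-499", "500-1499", "1500-2999", "3000+"),
                        (0.657, 0.080, 0.117, 0.146), rank_slope=-1.2,
                        outcome_coefs=(0.0, -0.25, -0.35, -0.55)),
        CategoricalSpec("chronic_disease", ("no", "yes"), (0.774, 0.226),
                        rank_slope=0.3, outcome_coefs=(0.0, 0.9)),
        CategoricalSpec("smoker", ("no", "yes"), (0.885, 0.115),
                        rank_slope=0.3, outcome_coefs=(0.0, -0.05)),
    )
    return SyntheticDesign(
        n=n, seed=seed, sex_split=0.569,
        weight_model=WeightSpec("gamma", 4.0, 0.25),
        covariates=covariates,
        outcome_model=OutcomeSpec(intercept_male=-1.6, intercept_female=0.3,
                                  rank_slope=1.2),
        waist_model=WaistSpec(),
    )
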