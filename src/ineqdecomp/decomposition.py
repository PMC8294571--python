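"""Decomposition of the Erreygers concentration index into covariate
contributions.

Following the regression-based (Wagstaff/van Doorslaer-style) approach, the
Erreygers index of a binary outcome decomposes over dummy-coded covariates as

    ECI = sum_k  [4 * beta_k^m * xbar_k] * CI_k  +  residual,

where beta_k^m is the marginal effect of dummy k from a weighted binomial GLM
evaluated at the vector of sample means, xbar_k the weighted dummy mean, and
CI_k the plain concentration index of the dummy over the same wealth ranks.
The bracketed term is reported as the "elasticity" column so that each row's
contribution is exactly elasticity * CI_k, and the rows plus the residual sum
to the total ECI.  The residual is defined by closure (total minus the summed
contributions) and cross-checked against 4x the generalized concentration
index of the GLM error term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .inequality import (
    RankedOutcome,
    concentration_index,
    erreygers_index,
    fractional_rank,
    generalized_concentration_index,
)
from .survey_data import (
    ConfigurationError,
    DataError,
    EstimationError,
    SurveyDataset,
)

__all__ = [
    "PartialEffects",
    "DecompositionRow",
    "DecompositionResult",
    "fit_partial_effects",
    "decompose_eci",
    "validate_adding_up",
]


# ---------------------------------------------------------------------------
# GLM partial effects
# ---------------------------------------------------------------------------

@dataclass
class PartialEffects:
    """Marginal effects at means from a weighted binomial GLM.

    ``effects`` maps (covariate, level) -> dy/dx of the level's dummy
    evaluated at the sample-mean covariate vector; ``x_bar`` the weighted
    dummy means; ``references`` the per-covariate reference ("Base") level.
    """

    effects: "dict[tuple[str, str], float]"
    x_bar: "dict[tuple[str, str], float]"
    references: "dict[str, str]"
    params: pd.Series
    p_bar: float
    fitted: np.ndarray
    bse: "dict[tuple[str, str], float]" = field(default_factory=dict)
    family: str = "binomial"
    link: str = "logit"


def _dummy_design(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str],
) -> tuple[pd.DataFrame, "dict[str, str]", "list[tuple[str, str]]"]:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(frame))}
    refs: dict[str, str] = {}
    keys: list[tuple[str, str]] = []
    for name in covariates:
        if name not in frame.columns:
            raise ConfigurationError(f"unknown covariate {name!r}")
        series = frame[name]
        levels = (
            list(series.cat.categories)
            if isinstance(series.dtype, pd.CategoricalDtype)
            else sorted(series.astype(str).unique())
        )
        ref = references.get(name, levels[0])
        if ref not in levels:
            raise ConfigurationError(f"reference level {ref!r} not in {name!r}")
        refs[name] = ref
        vals = series.astype(str).to_numpy()
        for level in levels:
            if level == ref:
                continue
            dummy = (vals == level).astype(float)
            if dummy.sum() == 0:
                warnings.warn(
                    f"covariate {name!r} level {level!r} is empty; dropped",
                    stacklevel=3,
                )
                continue
            cols[f"{name}[{level}]"] = dummy
            keys.append((name, level))
    return pd.DataFrame(cols, index=frame.index), refs, keys


def fit_partial_effects(
    dataset: SurveyDataset,
    outcome: str,
    covariates: Sequence[str],
    *,
    references: Mapping[str, str] | None = None,
    link: str = "logit",
) -> PartialEffects:
    """Weighted binomial GLM of the outcome on dummy-coded covariates, with
    marginal effects at means.

    With the logit link the partial effect of dummy k is
    ``beta_k * pbar * (1 - pbar)`` where ``pbar`` is the fitted probability
    at the weighted sample-mean design vector; with the identity link it is
    ``beta_k`` itself (sensitivity option).
    """
    f = dataset.frame
    if outcome not in f.columns:
        raise ConfigurationError(f"unknown outcome column {outcome!r}")
    y = f[outcome].to_numpy(dtype=float)
    if not set(np.unique(y[~np.isnan(y)])).issubset({0.0, 1.0}):
        raise DataError("outcome must be binary")
    w = f["weight"].to_numpy(dtype=float)
    X, refs, keys = _dummy_design(f, covariates, references or {})

    if link == "logit":
        fam = sm.families.Binomial()
    elif link == "identity":
        fam = sm.families.Binomial(link=sm.families.links.Identity())
    else:
        raise ConfigurationError(f"unknown link {link!r}")

    var_w = w / w.sum() * len(w)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=fam, var_weights=var_w).fit()
    except Exception as exc:  # separation, non-convergence, singular design
        raise EstimationError(f"GLM fit failed: {exc}") from exc
    if np.any(~np.isfinite(fit.params)):
        raise EstimationError("GLM produced non-finite coefficients (separation?)")
    if link == "logit" and np.any(np.abs(fit.params.to_numpy()) > 25.0):
        worst = fit.params.abs().idxmax()
        raise EstimationError(
            f"(quasi-)perfect separation detected for term {worst!r}"
        )

    wn = w / w.sum()
    xbar_vec = pd.Series(wn @ X.to_numpy(), index=X.columns)
    eta_bar = float(xbar_vec @ fit.params)
    p_bar = float(expit(eta_bar)) if link == "logit" else eta_bar
    scale = p_bar * (1.0 - p_bar) if link == "logit" else 1.0

    effects = {k: float(fit.params[f"{k[0]}[{k[1]}]"] * scale) for k in keys}
    x_bar = {k: float(xbar_vec[f"{k[0]}[{k[1]}]"]) for k in keys}
    # delta-method SE on the effect scale, holding the mean point fixed
    bse = {k: float(fit.bse[f"{k[0]}[{k[1]}]"] * scale) for k in keys}
    return PartialEffects(
        effects=effects, x_bar=x_bar, references=refs, params=fit.params,
        p_bar=p_bar, fitted=np.asarray(fit.fittedvalues, dtype=float),
        bse=bse, link=link,
    )


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecompositionRow:
    """One dummy's line of the decomposition table."""

    variable: str
    level: str
    elasticity: float
    ci_k: float
    contribution: float
    pct_contribution: float


@dataclass
class DecompositionResult:
    """Per-covariate contributions to the Erreygers index plus the residual.

    ``residual`` closes the adding-up identity (total minus summed
    contributions); ``residual_gci`` is the independent 4*GCI(error) check;
    ``adds_up_gap`` records the float discrepancy of the closed identity.
    """

    rows: list[DecompositionRow]
    residual: float
    total_eci: float
    adds_up_gap: float
    residual_gci: Optional[float] = None
    references: "dict[str, str]" = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "variable": r.variable, "level": r.level,
                    "elasticity": r.elasticity, "ci_k": r.ci_k,
                    "contribution": r.contribution, "pct": r.pct_contribution,
                }
                for r in self.rows
            ]
        )
        return df

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[tuple[str, str, float, float]],
        residual: float,
        total_eci: float,
    ) -> "DecompositionResult":
        """Build a result from externally supplied (variable, level,
        elasticity, ci_k) rows, e.g. a printed decomposition table, computing
        contributions and percentages through the package identities."""
        out = []
        for variable, level, elasticity, ci_k in rows:
            contribution = elasticity * ci_k
            pct = 100.0 * contribution / total_eci if total_eci != 0 else float("nan")
            out.append(DecompositionRow(variable, level, elasticity, ci_k,
                                        contribution, pct))
        gap = total_eci - (sum(r.contribution for r in out) + residual)
        return cls(rows=out, residual=residual, total_eci=total_eci, adds_up_gap=gap)


def decompose_eci(
    dataset: SurveyDataset,
    outcome: str,
    covariates: Sequence[str],
    *,
    references: Mapping[str, str] | None = None,
    rank: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    link: str = "logit",
) -> DecompositionResult:
    """Decompose the Erreygers index of a binary outcome into per-dummy
    contributions (elasticity x dummy concentration index) plus a residual.

    Ranks default to the weighted fractional rank of ``wealth_score`` within
    the supplied dataset (re-rank within subgroups by subsetting first).
    """
    f = dataset.frame
    w = f["weight"].to_numpy(dtype=float) if weights is None else np.asarray(weights, float)
    if len(w) != len(f):
        raise DataError("weights length does not match dataset")
    if rank is None:
        rank = fractional_rank(f["wealth_score"].to_numpy(dtype=float), w)
    else:
        rank = np.asarray(rank, dtype=float)
        if len(rank) != len(f):
            raise DataError("rank length does not match dataset")

    y = f[outcome].to_numpy(dtype=float)
    ranked_total = RankedOutcome.from_arrays(y, weights=w, rank=rank, bounds=(0.0, 1.0))
    total = erreygers_index(ranked_total, compute_se=False).value

    pe = fit_partial_effects(
        dataset, outcome, covariates, references=references, link=link
    )

    rows: list[DecompositionRow] = []
    for (variable, level), beta_m in pe.effects.items():
        dummy = (f[variable].astype(str).to_numpy() == level).astype(float)
        ranked_k = RankedOutcome.from_arrays(dummy, weights=w, rank=rank, bounds=(0.0, 1.0))
        ci_k = concentration_index(ranked_k, compute_se=False).value
        elasticity = 4.0 * beta_m * pe.x_bar[(variable, level)]
        contribution = elasticity * ci_k
        pct = 100.0 * contribution / total if total != 0 else float("nan")
        rows.append(DecompositionRow(variable, level, elasticity, ci_k, contribution, pct))

    explained = sum(r.contribution for r in rows)
    residual = total - explained
    eps = y - pe.fitted
    residual_gci = 4.0 * generalized_concentration_index(eps, ranked_total)
    gap = total - (explained + residual)
    return DecompositionResult(
        rows=rows, residual=residual, total_eci=total, adds_up_gap=gap,
        residual_gci=residual_gci, references=pe.references,
    )


def validate_adding_up(
    result: DecompositionResult,
    *,
    row_tol: float = 1e-12,
    sum_tol: float = 1e-9,
) -> dict:
    """Recompute the decomposition identities and report violations.

    Checks each row's ``contribution == elasticity * ci_k`` (within
    ``row_tol``) and the adding-up identity ``sum(contributions) + residual
    == total_eci`` (within ``sum_tol``)."""
    violations = []
    for r in result.rows:
        gap = r.contribution - r.elasticity * r.ci_k
        if abs(gap) > row_tol:
            violations.append({"variable": r.variable, "level": r.level, "gap": gap})
    total_gap = result.total_eci - (
        sum(r.contribution for r in result.rows) + result.residual
    )
    return {
        "sum_contributions": sum(r.contribution for r in result.rows),
        "residual": result.residual,
        "total_eci": result.total_eci,
        "gap": total_gap,
        "row_violations": violations,
        "ok": abs(total_gap) <= sum_tol and not violations,
    }
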