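"""Rank-based inequality measurement for health outcomes.

Implements the weighted (Lerman–Yitzhaki) fractional rank, the concentration
curve, the relative concentration index

    CI = (2 / mu) * cov_w(y, R),

and the Erreygers-corrected concentration index for bounded outcomes,

    ECI = 4 * mu / (b - a) * CI        (= 4 * mu * CI for a 0/1 outcome),

together with convenient-regression standard errors (heteroskedasticity-robust
by default, cluster-robust on the primary sampling unit when requested).

Positive index values indicate concentration of the outcome among the
wealthier (pro-rich inequality); negative values, among the poorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .survey_data import (
    DegenerateBoundsError,
    DegenerateVarianceError,
    UndefinedIndexError,
)

__all__ = [
    "fractional_rank",
    "RankedOutcome",
    "ConcentrationResult",
    "CurvePoints",
    "concentration_index",
    "erreygers_index",
    "index_standard_error",
    "concentration_curve",
    "convenient_regression_slope",
    "generalized_concentration_index",
]


def fractional_rank(wealth_score, weights=None) -> np.ndarray:
    """Weighted fractional rank of each record in the wealth distribution.

    Sort by wealth; a record's rank is the cumulative normalized weight of all
    strictly poorer records plus half its own tied group's normalized weight.
    Tied wealth scores share one rank, which keeps the weighted mean rank at
    exactly 0.5.  Ranks lie strictly inside (0, 1).
    """
    x = np.asarray(wealth_score, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("wealth scores must be finite")
    wn = w / w.sum()
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], wn[order]
    group_start = np.r_[True, np.diff(xs) != 0]
    gid = np.cumsum(group_start) - 1
    gw = np.bincount(gid, weights=ws)
    below = np.cumsum(gw) - gw
    r_group = below + gw / 2.0
    r = np.empty_like(x)
    r[order] = r_group[gid]
    return r


@dataclass
class RankedOutcome:
    """Outcome values paired with fractional wealth ranks and weights.

    ``w`` is normalized to sum to one; ``mu`` is the weighted outcome mean;
    ``bounds`` are the attainable outcome limits (a, b) — (0, 1) for binary
    outcomes — used by the Erreygers correction.
    """

    y: np.ndarray
    rank: np.ndarray
    w: np.ndarray
    mu: float
    bounds: Optional[tuple[float, float]]
    psu: Optional[np.ndarray] = None

    @classmethod
    def from_arrays(
        cls,
        y,
        wealth_score=None,
        weights=None,
        *,
        rank=None,
        bounds=None,
        psu=None,
    ) -> "RankedOutcome":
        y = np.asarray(y, dtype=float)
        n = len(y)
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        wn = w / w.sum()
        if rank is None:
            if wealth_score is None:
                raise ValueError("need wealth_score or precomputed rank")
            rank = fractional_rank(wealth_score, w)
        else:
            rank = np.asarray(rank, dtype=float)
        if bounds is None and set(np.unique(y)).issubset({0.0, 1.0}):
            bounds = (0.0, 1.0)
        mu = float(np.sum(wn * y))
        return cls(y=y, rank=rank, w=wn, mu=mu, bounds=bounds,
                   psu=None if psu is None else np.asarray(psu))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def is_binary(self) -> bool:
        return set(np.unique(self.y)).issubset({0.0, 1.0})


@dataclass
class ConcentrationResult:
    """Point estimate of a concentration index with its standard error."""

    index_type: str          # "CI" or "ECI"
    value: float
    se: float
    n: int
    mu: float
    se_method: str
    degenerate: bool = False


@dataclass
class CurvePoints:
    """Concentration-curve coordinates: cumulative population share (x) vs
    cumulative outcome share (y), wealth-ranked, from (0,0) to (1,1)."""

    x: np.ndarray
    y: np.ndarray

    def auc(self) -> float:
        return float(np.trapezoid(self.y, self.x))


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

def _weighted_cov_y_rank(ranked: RankedOutcome) -> float:
    rbar = float(np.sum(ranked.w * ranked.rank))
    return float(np.sum(ranked.w * (ranked.y - ranked.mu) * (ranked.rank - rbar)))


def concentration_index(
    ranked: RankedOutcome,
    *,
    se_method: str = "convenient_regression",
    compute_se: bool = True,
) -> ConcentrationResult:
    """Relative concentration index CI = (2/mu) * cov_w(y, R).

    Undefined at mu = 0.  For a binary outcome with mu = 1 the covariance is
    identically zero; CI = 0 is returned flagged as degenerate.
    """
    if ranked.mu == 0:
        raise UndefinedIndexError("concentration index undefined: outcome mean is 0")
    if np.ptp(ranked.y) == 0:
        # constant outcome: covariance identically zero; flag the binary
        # all-ones boundary case as degenerate
        return ConcentrationResult(
            index_type="CI", value=0.0, se=0.0, n=ranked.n, mu=ranked.mu,
            se_method=se_method, degenerate=bool(ranked.is_binary),
        )
    degenerate = False
    value = 2.0 * _weighted_cov_y_rank(ranked) / ranked.mu
    se = 0.0
    if compute_se and not degenerate:
        se = index_standard_error(ranked, method=se_method, index_type="CI")
    return ConcentrationResult(
        index_type="CI", value=float(value), se=float(se), n=ranked.n,
        mu=ranked.mu, se_method=se_method, degenerate=degenerate,
    )


def erreygers_index(
    ranked: RankedOutcome,
    *,
    se_method: str = "convenient_regression",
    compute_se: bool = True,
) -> ConcentrationResult:
    """Erreygers concentration index, ECI = 4*mu*CI/(b - a).

    The correction keeps the attainable range at [-1, 1] for bounded (notably
    binary) outcomes whatever the prevalence.
    """
    if ranked.bounds is None:
        raise DegenerateBoundsError("outcome bounds required for the Erreygers index")
    a, b = ranked.bounds
    if not b > a:
        raise DegenerateBoundsError(f"degenerate outcome bounds ({a}, {b})")
    ci = concentration_index(ranked, compute_se=False)
    value = 4.0 * ranked.mu * ci.value / (b - a)
    se = 0.0
    if compute_se and not ci.degenerate:
        se = index_standard_error(ranked, method=se_method, index_type="ECI")
    return ConcentrationResult(
        index_type="ECI", value=float(value), se=float(se), n=ranked.n,
        mu=ranked.mu, se_method=se_method, degenerate=ci.degenerate,
    )


def generalized_concentration_index(values, ranked: RankedOutcome) -> float:
    """Generalized CI of an arbitrary (possibly signed, zero-mean) variable
    over the same ranks and weights: GCI = 2 * cov_w(values, R)."""
    v = np.asarray(values, dtype=float)
    rbar = float(np.sum(ranked.w * ranked.rank))
    vbar = float(np.sum(ranked.w * v))
    return 2.0 * float(np.sum(ranked.w * (v - vbar) * (ranked.rank - rbar)))


# ---------------------------------------------------------------------------
# Standard errors (convenient regression)
# ---------------------------------------------------------------------------

def _convenient_lhs(ranked: RankedOutcome, index_type: str) -> np.ndarray:
    rbar = float(np.sum(ranked.w * ranked.rank))
    var_r = float(np.sum(ranked.w * (ranked.rank - rbar) ** 2))
    if index_type == "CI":
        return 2.0 * var_r * ranked.y / ranked.mu
    if index_type == "ECI":
        a, b = ranked.bounds if ranked.bounds is not None else (0.0, 1.0)
        return 8.0 * var_r * ranked.y / (b - a)
    raise ValueError(f"unknown index_type {index_type!r}")


def _wls_fit(ranked: RankedOutcome, index_type: str, cov_type: str, cov_kwds=None):
    lhs = _convenient_lhs(ranked, index_type)
    X = sm.add_constant(ranked.rank)
    model = sm.WLS(lhs, X, weights=ranked.w)
    return model.fit(cov_type=cov_type, cov_kwds=cov_kwds or {})


def convenient_regression_slope(ranked: RankedOutcome, index_type: str = "CI") -> float:
    """Index estimate obtained as the slope of the convenient WLS regression
    of the transformed outcome on the fractional rank.  Algebraically equal to
    the covariance-formula estimate; serves as an independent numerical route."""
    return float(_wls_fit(ranked, index_type, "nonrobust").params[1])


def index_standard_error(
    ranked: RankedOutcome,
    *,
    method: str = "convenient_regression",
    index_type: str = "ECI",
) -> float:
    """Standard error of CI or ECI from the convenient regression.

    ``convenient_regression`` uses a heteroskedasticity-robust (HC1)
    covariance; ``cluster_robust`` clusters on the primary sampling unit
    carried by the RankedOutcome.
    """
    if ranked.n < 2:
        raise DegenerateVarianceError("need at least two records for a standard error")
    if np.ptp(ranked.y) == 0:
        return 0.0
    if method == "convenient_regression":
        fit = _wls_fit(ranked, index_type, "HC1")
    elif method == "cluster_robust":
        if ranked.psu is None:
            raise DegenerateVarianceError("cluster_robust requires psu identifiers")
        if len(np.unique(ranked.psu)) < 2:
            raise DegenerateVarianceError("cluster_robust requires at least two PSUs")
        fit = _wls_fit(ranked, index_type, "cluster", {"groups": ranked.psu})
    else:
        raise ValueError(f"unknown SE method {method!r}")
    return float(fit.bse[1])


# ---------------------------------------------------------------------------
# Concentration curve
# ---------------------------------------------------------------------------

def concentration_curve(ranked: RankedOutcome, n_points: int | None = None) -> CurvePoints:
    """Concentration curve: cumulative normalized weight against cumulative
    weighted outcome share, in wealth-rank order, with exact (0,0) and (1,1)
    endpoints.  With ``n_points`` the record-level polyline is linearly
    resampled onto an even grid (endpoints kept exact)."""
    if ranked.mu == 0:
        raise UndefinedIndexError("concentration curve undefined: outcome mean is 0")
    order = np.argsort(ranked.rank, kind="stable")
    w = ranked.w[order]
    share = ranked.w[order] * ranked.y[order]
    x = np.concatenate([[0.0], np.cumsum(w)])
    y = np.concatenate([[0.0], np.cumsum(share)])
    x[-1] = 1.0
    y = y / y[-1]
    y[-1] = 1.0
    if n_points is not None:
        grid = np.linspace(0.0, 1.0, int(n_points))
        y = np.interp(grid, x, y)
        x = grid
        y[0], y[-1] = 0.0, 1.0
    return CurvePoints(x=x, y=y)
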