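"""Abdominal-obesity classification, survey-weighted descriptives, and direct
age-standardization.

Three waist-circumference cut-off systems are frozen constants:

* IDF    — >= 90 cm (men), >= 80 cm (women); the primary definition for
  South/Central American populations;
* ATPIII — > 102 cm (men), > 88 cm (women);
* LASO   — >= 97 cm (men), >= 94 cm (women).

Weighted prevalences and means carry design-based uncertainty: a Taylor-
linearized clustered variance when PSU identifiers are available, otherwise a
weighted-binomial interval (Wilson on the Kish effective sample size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .survey_data import ConfigurationError, SurveyDataset

__all__ = [
    "CutoffCriterion",
    "CUTOFFS",
    "classify_abdominal_obesity",
    "weighted_prevalence",
    "weighted_mean_se",
    "StandardPopulation",
    "WHO_WORLD_STANDARD",
    "adult_standard",
    "age_standardize",
    "ADULT_BAND_EDGES",
]


# ---------------------------------------------------------------------------
# Cut-off criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffCriterion:
    """Sex-specific waist-circumference threshold with its comparator."""

    name: str
    male_threshold_cm: float
    male_comparator: str    # "ge" or "gt"
    female_threshold_cm: float
    female_comparator: str


CUTOFFS: dict[str, CutoffCriterion] = {
    "IDF": CutoffCriterion("IDF", 90.0, "ge", 80.0, "ge"),
    "ATPIII": CutoffCriterion("ATPIII", 102.0, "gt", 88.0, "gt"),
    "LASO": CutoffCriterion("LASO", 97.0, "ge", 94.0, "ge"),
}

_COMPARE = {"ge": np.greater_equal, "gt": np.greater}


def classify_abdominal_obesity(waist_cm, sex, criterion: CutoffCriterion | str):
    """Binary abdominal-obesity status under a cut-off criterion.

    Accepts scalars or aligned arrays.  Missing waist values yield NaN (a
    missing-outcome marker), never a silent negative.
    """
    if isinstance(criterion, str):
        try:
            criterion = CUTOFFS[criterion]
        except KeyError:
            raise ConfigurationError(f"unknown cut-off criterion {criterion!r}") from None
    waist = np.asarray(waist_cm, dtype=float)
    sex_arr = np.asarray(sex, dtype=object)
    scalar = waist.ndim == 0
    waist = np.atleast_1d(waist)
    sex_arr = np.atleast_1d(sex_arr)
    male = sex_arr == "male"
    thr = np.where(male, criterion.male_threshold_cm, criterion.female_threshold_cm)
    m_cmp = _COMPARE[criterion.male_comparator]
    f_cmp = _COMPARE[criterion.female_comparator]
    out = np.where(male, m_cmp(waist, thr), f_cmp(waist, thr)).astype(float)
    out[np.isnan(waist)] = np.nan
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Weighted prevalence and means
# ---------------------------------------------------------------------------

def _taylor_se(y: np.ndarray, w: np.ndarray, est: float,
               psu: np.ndarray, stratum: np.ndarray) -> float:
    """Taylor-linearized SE of the ratio estimator sum(w*y)/sum(w), treating
    PSUs as first-stage clusters within strata (with-replacement formula)."""
    total_w = w.sum()
    z = w * (y - est) / total_w
    df = pd.DataFrame({"z": z, "psu": psu, "stratum": stratum})
    var = 0.0
    for _, g in df.groupby("stratum", observed=True):
        totals = g.groupby("psu", observed=True)["z"].sum().to_numpy()
        nh = len(totals)
        if nh < 2:
            continue
        var += nh / (nh - 1) * np.sum((totals - totals.mean()) ** 2)
    return float(np.sqrt(var))


def _effective_n(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / np.sum(w ** 2))


def _cell_prevalence(y, w, psu, stratum, method: str) -> tuple[float, float, float, str]:
    est = float(np.sum(w * y) / np.sum(w))
    if np.ptp(y) == 0:
        # zero design variance: degenerate interval at the estimate
        return est, est, est, "degenerate"
    if method == "taylor":
        se = _taylor_se(y, w, est, psu, stratum)
        lo = max(0.0, est - 1.959963984540054 * se)
        hi = min(1.0, est + 1.959963984540054 * se)
        return est, lo, hi, "taylor_psu"
    n_eff = _effective_n(w)
    lo, hi = _wilson(est, n_eff)
    return est, lo, hi, "wilson_neff"


def _wilson(p: float, n: float, z: float = 1.959963984540054) -> tuple[float, float]:
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def _resolve_method(frame: pd.DataFrame, method: str) -> str:
    if method == "auto":
        return "taylor" if frame["psu"].notna().all() else "wilson"
    if method in ("taylor", "wilson"):
        return method
    raise ConfigurationError(f"unknown variance method {method!r}")


def _iter_cells(frame: pd.DataFrame, by: Sequence[str]):
    if not by:
        yield (), frame
        return
    for keys, g in frame.groupby(list(by), observed=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        yield keys, g


def weighted_prevalence(
    dataset: SurveyDataset,
    outcome: str,
    by: Sequence[str] = (),
    *,
    variance: str = "auto",
) -> pd.DataFrame:
    """Survey-weighted prevalence of a binary outcome with 95% CI, optionally
    stratified by covariates.  Cells with no usable records are omitted with
    a warning."""
    f = dataset.frame
    for name in by:
        if name not in f.columns:
            raise ConfigurationError(f"unknown covariate {name!r}")
    if outcome not in f.columns:
        raise ConfigurationError(f"unknown outcome column {outcome!r}")
    method = _resolve_method(f, variance)
    rows = []
    for keys, g in _iter_cells(f, by):
        y = g[outcome].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if not ok.any() or g["weight"].to_numpy()[ok].sum() <= 0:
            warnings.warn(f"cell {keys!r} has no usable records; omitted", stacklevel=2)
            continue
        y = y[ok]
        w = g["weight"].to_numpy(dtype=float)[ok]
        psu = g["psu"].to_numpy()[ok]
        stratum = g["stratum"].to_numpy()[ok]
        est, lo, hi, used = _cell_prevalence(y, w, psu, stratum, method)
        rows.append(
            dict(zip(by, keys))
            | {
                "estimate": est, "ci_low": lo, "ci_high": hi,
                "n_unweighted": int(ok.sum()), "weighted_total": float(w.sum()),
                "method": used,
            }
        )
    return pd.DataFrame(rows)


def weighted_mean_se(
    dataset: SurveyDataset,
    value: str,
    by: Sequence[str] = (),
    *,
    variance: str = "auto",
) -> pd.DataFrame:
    """Survey-weighted mean of a continuous column with its standard error
    (same variance machinery as :func:`weighted_prevalence`); missing values
    are excluded cell-wise; a single-record cell yields SE = NaN."""
    f = dataset.frame
    for name in by:
        if name not in f.columns:
            raise ConfigurationError(f"unknown covariate {name!r}")
    if value not in f.columns:
        raise ConfigurationError(f"unknown value column {value!r}")
    method = _resolve_method(f, variance)
    rows = []
    for keys, g in _iter_cells(f, by):
        x = g[value].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if not ok.any():
            warnings.warn(f"cell {keys!r} has no usable records; omitted", stacklevel=2)
            continue
        x = x[ok]
        w = g["weight"].to_numpy(dtype=float)[ok]
        mean = float(np.sum(w * x) / w.sum())
        if len(x) < 2:
            se = float("nan")
        elif method == "taylor":
            se = _taylor_se(x, w, mean, g["psu"].to_numpy()[ok], g["stratum"].to_numpy()[ok])
        else:
            se = float(np.sqrt(np.sum(w ** 2 * (x - mean) ** 2)) / w.sum())
        rows.append(
            dict(zip(by, keys))
            | {"mean": mean, "se": se, "n_unweighted": int(ok.sum()),
               "weighted_total": float(w.sum())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Direct age-standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardPopulation:
    """Reference age structure: ordered bands with weights summing to one."""

    bands: tuple[str, ...]
    weights: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ConfigurationError("standard-population weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"standard-population weights must sum to 1 (got {w.sum()!r})"
            )
        if len(self.bands) != len(self.weights):
            raise ConfigurationError("bands and weights must align")


# WHO 2001 world-standard population, percent by 5-year band (0-4 ... 85+).
# The printed percents sum to 100.03; they are normalized on construction.
_WHO_BANDS = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
)
_WHO_PCT = np.array([
    8.86, 8.69, 8.60, 8.47, 8.22, 7.93, 7.61, 7.15, 6.59, 6.04, 5.37, 4.55,
    3.72, 2.96, 2.21, 1.52, 0.91, 0.63,
])

WHO_WORLD_STANDARD = StandardPopulation(
    bands=_WHO_BANDS,
    weights=tuple(_WHO_PCT / _WHO_PCT.sum()),
    label="WHO World Standard",
)

#: Adult analysis bands and their age edges (upper edge exclusive; None = open).
ADULT_BAND_EDGES: dict[str, tuple[int, Optional[int]]] = {
    "18-29": (18, 30),
    "30-59": (30, 60),
    "60+": (60, None),
}


def adult_standard(standard: StandardPopulation = WHO_WORLD_STANDARD) -> StandardPopulation:
    """Collapse a 5-year-band standard onto the adult analysis bands
    18-29 / 30-59 / 60+, splitting straddling bands uniformly by year of age
    (the 15-19 band contributes 2/5 of its weight to 18-29) and renormalizing
    to the adult population."""
    w = dict(zip(standard.bands, standard.weights))
    coll = {"18-29": 0.0, "30-59": 0.0, "60+": 0.0}
    for band, weight in w.items():
        if band.endswith("+"):
            lo, hi = int(band[:-1]), 200
        else:
            lo, hi = (int(s) for s in band.split("-"))
            hi += 1  # make exclusive
        for target, (tlo, thi) in ADULT_BAND_EDGES.items():
            thi = 200 if thi is None else thi
            overlap = max(0, min(hi, thi) - max(lo, tlo))
            if overlap:
                coll[target] += weight * overlap / (hi - lo)
    total = sum(coll.values())
    return StandardPopulation(
        bands=tuple(coll), weights=tuple(v / total for v in coll.values()),
        label=f"{standard.label} (adult 18+)",
    )


def age_standardize(
    cell_estimates: Mapping[str, float] | pd.Series,
    standard: StandardPopulation,
    band_mapping: Mapping[str, str] | None = None,
) -> float:
    """Directly age-standardized prevalence: the standard-weighted average of
    band-specific prevalences.  ``band_mapping`` maps standard bands onto the
    (possibly coarser) bands of ``cell_estimates``; an unmapped, unmatched
    band is a configuration error."""
    est = dict(cell_estimates)
    mapping = dict(band_mapping or {})
    total = 0.0
    for band, weight in zip(standard.bands, standard.weights):
        target = mapping.get(band, band)
        if target not in est:
            raise ConfigurationError(
                f"standard band {band!r} has no estimate (resolved to {target!r}) "
                "and no band mapping was provided"
            )
        total += weight * float(est[target])
    return total


def age_band_column(age_years, edges: Mapping[str, tuple[int, Optional[int]]] = ADULT_BAND_EDGES):
    """Map ages onto labelled bands (NaN outside every band)."""
    age = np.asarray(age_years, dtype=float)
    out = np.full(len(age), None, dtype=object)
    for label, (lo, hi) in edges.items():
        hi_v = np.inf if hi is None else hi
        out[(age >= lo) & (age < hi_v)] = label
    return pd.Series(out, name="age_band")
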