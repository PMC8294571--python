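"""Weighted survey microdata: ingestion, eligibility filtering, multi-year
pooling, and wealth-quintile assignment.

The canonical in-memory container is a :class:`SurveyDataset` — a thin wrapper
around a tidy :class:`pandas.DataFrame` with one row per respondent and a fixed
core column set, plus an ordered categorical schema for the sociodemographic
covariates.  All downstream stages (descriptives, concentration indices,
decomposition) consume this container.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CORE_COLUMNS",
    "SurveyDataset",
    "read_survey_table",
    "write_survey_table",
    "apply_eligibility",
    "pool_datasets",
    "assign_wealth_quintiles",
    "QUINTILE_LABELS",
    "IneqdecompError",
    "ConfigurationError",
    "DataError",
    "EmptyInputError",
    "IncompatibleDatasetsError",
    "EstimationError",
    "UndefinedIndexError",
    "DegenerateBoundsError",
    "DegenerateVarianceError",
    "DegenerateQuintilesWarning",
]


# ---------------------------------------------------------------------------
# Errors (shared across the package; CLI maps these onto exit codes)
# ---------------------------------------------------------------------------

class IneqdecompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IneqdecompError):
    """Invalid configuration: missing columns, unknown names, bad mappings."""


class DataError(IneqdecompError):
    """Input data violates a precondition."""


class EmptyInputError(DataError):
    """No usable records remain."""


class IncompatibleDatasetsError(DataError):
    """Datasets cannot be combined (schema mismatch)."""


class EstimationError(IneqdecompError):
    """A statistical estimation step failed."""


class UndefinedIndexError(EstimationError):
    """Concentration index undefined (zero outcome mean)."""


class DegenerateBoundsError(EstimationError):
    """Erreygers correction undefined: outcome bounds coincide."""


class DegenerateVarianceError(EstimationError):
    """Variance estimator degenerate (e.g. a single cluster)."""


class DegenerateQuintilesWarning(UserWarning):
    """Fewer distinct wealth values than quintiles."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

#: Fixed order of the non-covariate columns in the canonical tidy table.
CORE_COLUMNS = (
    "person_id",
    "year",
    "sex",
    "age_years",
    "waist_cm",
    "wealth_score",
    "weight",
    "psu",
    "stratum",
    "pregnant",
)

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male", "man": "male", "hombre": "male",
    "female": "female", "f": "female", "2": "female", "woman": "female",
    "mujer": "female",
}


@dataclass
class SurveyDataset:
    """Person-level survey records plus the covariate category schema.

    ``frame`` holds the :data:`CORE_COLUMNS` followed by one column per
    covariate (ordered pandas Categorical).  ``covariates`` maps covariate
    name to its ordered category labels; the first label is treated as the
    reference ("Base") level by the decomposition.
    """

    frame: pd.DataFrame
    covariates: "OrderedDict[str, list[str]]" = field(default_factory=OrderedDict)

    def __post_init__(self) -> None:
        self.covariates = OrderedDict(
            (k, list(v)) for k, v in self.covariates.items()
        )
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        f = self.frame
        missing = [c for c in CORE_COLUMNS if c not in f.columns]
        if missing:
            raise ConfigurationError(f"canonical columns missing: {missing}")
        if len(f) == 0:
            raise EmptyInputError("dataset has no records")
        w = f["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w) & (w > 0)):
            raise DataError("all weights must be finite and > 0")
        ws = f["wealth_score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ws)):
            raise DataError("wealth_score must be finite for every record")
        waist = f["waist_cm"].to_numpy(dtype=float)
        present = ~np.isnan(waist)
        if not np.all(waist[present] > 0):
            raise DataError("waist_cm must be > 0 where present")
        dup = f.duplicated(subset=["year", "person_id"])
        if dup.any():
            raise DataError("duplicated person_id within a year")
        for name, levels in self.covariates.items():
            if name not in f.columns:
                raise ConfigurationError(f"covariate column missing: {name!r}")
            observed = set(f[name].dropna().astype(str).unique())
            unknown = observed - set(levels)
            if unknown:
                raise DataError(
                    f"covariate {name!r} has labels outside its schema: {sorted(unknown)}"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def total_weight(self) -> float:
        return float(self.frame["weight"].sum())

    def subset(self, mask) -> "SurveyDataset":
        """Row subset preserving the covariate schema."""
        sub = self.frame.loc[mask].reset_index(drop=True)
        if len(sub) == 0:
            raise EmptyInputError("subset removed every record")
        return SurveyDataset(sub, self.covariates)

    def replace_frame(self, frame: pd.DataFrame) -> "SurveyDataset":
        return SurveyDataset(frame.reset_index(drop=True), self.covariates)


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

_REQUIRED_ROLES = ("sex", "age", "waist", "wealth", "weight")


def read_survey_table(
    source: str | IO[str],
    schema: Mapping[str, object],
    *,
    sep: str = ",",
    year: str = "y0",
) -> tuple[SurveyDataset, dict[str, int]]:
    """Read a delimited table into a :class:`SurveyDataset`.

    ``schema`` maps column roles to column names in the file.  Required roles:
    ``sex, age, waist, wealth, weight``; optional: ``person_id, psu, stratum,
    pregnant, year``; ``covariates`` maps covariate name -> column name, and
    ``covariate_levels`` (optional) covariate name -> ordered labels.

    Rows violating hard invariants (non-positive weight, non-finite wealth,
    invalid sex code, negative age, non-positive waist) are dropped and counted
    per reason.  Returns ``(dataset, drop_counts)``.
    """
    raw = pd.read_csv(source, sep=sep, dtype=str)
    for role in _REQUIRED_ROLES:
        if role not in schema:
            raise ConfigurationError(f"schema missing required role {role!r}")
        col = schema[role]
        if col not in raw.columns:
            raise ConfigurationError(
                f"required column {col!r} (role {role!r}) not found in input"
            )

    n = len(raw)
    f = pd.DataFrame(index=raw.index)
    f["person_id"] = (
        raw[schema["person_id"]].astype(str)
        if "person_id" in schema and schema["person_id"] in raw.columns
        else np.arange(n).astype(str)
    )
    f["year"] = (
        raw[schema["year"]].astype(str)
        if "year" in schema and schema["year"] in raw.columns
        else year
    )
    sex_raw = raw[schema["sex"]].astype(str).str.strip().str.lower()
    f["sex"] = sex_raw.map(_SEX_ALIASES)
    f["age_years"] = pd.to_numeric(raw[schema["age"]], errors="coerce")
    f["waist_cm"] = pd.to_numeric(raw[schema["waist"]], errors="coerce")
    f["wealth_score"] = pd.to_numeric(raw[schema["wealth"]], errors="coerce")
    f["weight"] = pd.to_numeric(raw[schema["weight"]], errors="coerce")
    for opt in ("psu", "stratum"):
        f[opt] = (
            raw[schema[opt]].astype("string")
            if opt in schema and schema[opt] in raw.columns
            else pd.NA
        )
    if "pregnant" in schema and schema["pregnant"] in raw.columns:
        preg = raw[schema["pregnant"]].astype(str).str.strip().str.lower()
        f["pregnant"] = preg.isin({"1", "true", "yes", "si", "sí"})
    else:
        f["pregnant"] = False

    covs: OrderedDict[str, list[str]] = OrderedDict()
    level_spec = schema.get("covariate_levels", {}) or {}
    for name, col in (schema.get("covariates", {}) or {}).items():
        if col not in raw.columns:
            raise ConfigurationError(f"covariate column {col!r} not found in input")
        vals = raw[col].astype(str).str.strip()
        vals = vals.where(~vals.isin({"", "nan", "NA"}), other="missing")
        levels = list(level_spec.get(name) or sorted(vals.unique()))
        if "missing" in set(vals) and "missing" not in levels:
            levels.append("missing")
        f[name] = pd.Categorical(vals, categories=levels, ordered=True)
        covs[name] = levels

    # hard-invariant filtering, counted by first failing reason
    drops: dict[str, int] = {}
    keep = np.ones(n, dtype=bool)
    checks = [
        ("invalid_sex", f["sex"].isna().to_numpy()),
        ("invalid_age", (~np.isfinite(f["age_years"].to_numpy(dtype=float)))
         | (f["age_years"].to_numpy(dtype=float) < 0)),
        ("nonpositive_weight", (~np.isfinite(f["weight"].to_numpy(dtype=float)))
         | (f["weight"].to_numpy(dtype=float) <= 0)),
        ("nonfinite_wealth", ~np.isfinite(f["wealth_score"].to_numpy(dtype=float))),
        ("invalid_waist", (~f["waist_cm"].isna().to_numpy())
         & ~(f["waist_cm"].to_numpy(dtype=float) > 0)),
    ]
    for reason, bad in checks:
        newly = bad & keep
        if newly.any():
            drops[reason] = int(newly.sum())
        keep &= ~bad
    if not keep.any():
        raise EmptyInputError("no rows survived invariant filtering")

    f = f.loc[keep].reset_index(drop=True)
    order = list(CORE_COLUMNS) + list(covs)
    return SurveyDataset(f[order], covs), drops


def write_survey_table(dataset: SurveyDataset, path: str | IO[str]) -> None:
    """Write the canonical tidy table (fixed column order) as CSV."""
    cols = list(CORE_COLUMNS) + list(dataset.covariates)
    dataset.frame[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def apply_eligibility(
    dataset: SurveyDataset,
    *,
    min_age: int = 18,
    require_waist: bool = True,
    exclude_pregnant: bool = True,
) -> tuple[SurveyDataset, "OrderedDict[str, int]"]:
    """Apply the study inclusion criteria (adults with a waist measurement,
    non-pregnant), returning the retained dataset and exclusion counts in
    fixed order (age, pregnancy, missing waist).

    Each record is counted once, under the first criterion it fails.
    """
    f = dataset.frame
    counts: OrderedDict[str, int] = OrderedDict(
        [("age", 0), ("pregnancy", 0), ("missing_waist", 0)]
    )
    keep = np.ones(len(f), dtype=bool)

    bad_age = f["age_years"].to_numpy(dtype=float) < float(min_age)
    counts["age"] = int((bad_age & keep).sum())
    keep &= ~bad_age

    if exclude_pregnant and "pregnant" in f.columns:
        preg = f["pregnant"].fillna(False).astype(bool).to_numpy()
        counts["pregnancy"] = int((preg & keep).sum())
        keep &= ~preg

    if require_waist:
        noww = f["waist_cm"].isna().to_numpy()
        counts["missing_waist"] = int((noww & keep).sum())
        keep &= ~noww

    if not keep.any():
        raise EmptyInputError("eligibility criteria excluded every record")
    return dataset.subset(keep), counts


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool_datasets(
    datasets: Sequence[SurveyDataset],
    weight_policy: str = "per_year_normalized",
) -> SurveyDataset:
    """Pool survey years into a single dataset.

    ``per_year_normalized`` rescales each year's expansion factors so the
    year's weight total equals its unweighted record count — every year then
    contributes to weighted estimates in proportion to its sample size.
    ``as_is`` leaves the expansion factors untouched.
    """
    if weight_policy not in ("as_is", "per_year_normalized"):
        raise ConfigurationError(f"unknown weight_policy {weight_policy!r}")
    if len(datasets) == 0:
        raise ConfigurationError("need at least one dataset to pool")
    schema0 = datasets[0].covariates
    for d in datasets[1:]:
        if d.covariates != schema0:
            raise IncompatibleDatasetsError("covariate schemas differ across datasets")
    frame = pd.concat([d.frame for d in datasets], ignore_index=True)
    if weight_policy == "per_year_normalized":
        frame = frame.copy()
        totals = frame.groupby("year", observed=True)["weight"].transform("sum")
        sizes = frame.groupby("year", observed=True)["weight"].transform("size")
        frame["weight"] = frame["weight"] * sizes / totals
    return SurveyDataset(frame, schema0)


# ---------------------------------------------------------------------------
# Wealth quintiles
# ---------------------------------------------------------------------------

def assign_wealth_quintiles(dataset: SurveyDataset) -> pd.Series:
    """Assign weighted wealth quintiles Q1 (poorest) .. Q5 (richest).

    Boundaries sit at cumulative weight fractions 0.2/0.4/0.6/0.8 of the
    wealth-sorted population.  Records tied on wealth_score form one group and
    share a quintile.  A group straddling a cut is assigned to the quintile
    containing the midpoint of its cumulative-weight interval (ties at a cut
    go to the lower quintile), so each group lands where the majority of its
    mass accumulates first.
    """
    f = dataset.frame
    wealth = f["wealth_score"].to_numpy(dtype=float)
    w = f["weight"].to_numpy(dtype=float)
    if len(np.unique(wealth)) < 5:
        warnings.warn(
            "fewer than 5 distinct wealth values; quintiles are degenerate",
            DegenerateQuintilesWarning,
            stacklevel=2,
        )
    order = np.argsort(wealth, kind="stable")
    ws, wts = wealth[order], w[order]
    total = wts.sum()
    # group ties
    group_start = np.r_[True, np.diff(ws) != 0]
    gid = np.cumsum(group_start) - 1
    gw = np.bincount(gid, weights=wts)
    cum = np.cumsum(gw)
    mid_frac = (cum - gw / 2.0) / total
    # quintile j = smallest j with midpoint <= 0.2 j  (ties at a cut -> lower)
    q_group = np.minimum(np.ceil(mid_frac / 0.2 - 1e-12).astype(int), 5)
    q_group = np.maximum(q_group, 1)
    q_sorted = q_group[gid]
    q = np.empty(len(f), dtype=int)
    q[order] = q_sorted
    labels = pd.Categorical.from_codes(q - 1, categories=list(QUINTILE_LABELS), ordered=True)
    return pd.Series(labels, index=f.index, name="wealth_quintile")
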