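"""Config-driven end-to-end analysis runner.

Given person-level survey files (or a pre-built dataset), reproduces the full
analysis shape: eligibility filtering -> multi-year pooling -> wealth
quintiles -> weighted descriptives -> concentration curves per sex ->
concentration/Erreygers indices per sex -> GLM decomposition per sex, with a
deterministic, fixed output layout and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import decompose_eci
from .descriptives import (
    CUTOFFS,
    adult_standard,
    age_band_column,
    age_standardize,
    classify_abdominal_obesity,
    weighted_mean_se,
    weighted_prevalence,
)
from .inequality import (
    RankedOutcome,
    concentration_curve,
    concentration_index,
    erreygers_index,
    fractional_rank,
)
from .survey_data import (
    ConfigurationError,
    SurveyDataset,
    apply_eligibility,
    assign_wealth_quintiles,
    pool_datasets,
    read_survey_table,
)

__all__ = ["RunConfig", "run_analysis"]

log = logging.getLogger("ineqdecomp")


@dataclass
class RunConfig:
    """Full parameterization of an analysis run."""

    inputs: list[dict]                  # [{path, year, sep?}] sharing one schema
    schema: dict                        # column-role mapping (see read_survey_table)
    out_dir: str
    criterion: str = "IDF"
    extra_criteria: tuple[str, ...] = ()
    min_age: int = 18
    require_waist: bool = True
    exclude_pregnant: bool = True
    weight_policy: str = "per_year_normalized"
    rank_scope: str = "within-sex"      # or "pooled"
    se_method: str = "convenient_regression"
    covariates: list[str] = field(default_factory=list)
    references: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for crit in (self.criterion, *self.extra_criteria):
            if crit not in CUTOFFS:
                raise ConfigurationError(f"unknown criterion {crit!r}")
        if self.rank_scope not in ("within-sex", "pooled"):
            raise ConfigurationError(f"unknown rank_scope {self.rank_scope!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        for item in cfg.inputs:
            if not Path(item["path"]).exists():
                raise ConfigurationError(f"input file not found: {item['path']}")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[SurveyDataset, dict]:
    datasets, drops = [], {}
    for item in config.inputs:
        ds, d = read_survey_table(
            item["path"], config.schema,
            sep=item.get("sep", ","), year=str(item.get("year", "y0")),
        )
        datasets.append(ds)
        drops[str(item.get("year", "y0"))] = d
    pooled = pool_datasets(datasets, config.weight_policy)
    return pooled, drops


def _sex_groups(dataset: SurveyDataset):
    for sex in ("male", "female"):
        mask = (dataset.frame["sex"] == sex).to_numpy()
        if mask.any():
            yield sex, dataset.subset(mask)


def run_analysis(
    config: RunConfig,
    dataset: SurveyDataset | None = None,
) -> dict:
    """Run the full pipeline; returns a bundle of output paths and key
    results.  Deterministic given (inputs, config, seed).  Any stage failure
    aborts with the stage named and removes partially written outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(name: str, df: pd.DataFrame) -> Path:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        return path

    stage = "load"
    try:
        t0 = time.perf_counter()
        drops: dict = {}
        if dataset is None:
            dataset, drops = _load_inputs(config)
        log.info("load: %d records (%.2fs)", dataset.n, time.perf_counter() - t0)

        stage = "eligibility"
        dataset, exclusions = apply_eligibility(
            dataset, min_age=config.min_age,
            require_waist=config.require_waist,
            exclude_pregnant=config.exclude_pregnant,
        )
        log.info("eligibility: %d retained, excluded %s", dataset.n, dict(exclusions))

        stage = "quintiles"
        frame = dataset.frame.copy()
        frame["wealth_quintile"] = assign_wealth_quintiles(dataset).to_numpy()
        covs = dict(dataset.covariates)
        covs["wealth_quintile"] = ["Q1", "Q2", "Q3", "Q4", "Q5"]
        dataset = SurveyDataset(frame, covs)

        stage = "classification"
        frame = dataset.frame.copy()
        for crit in (config.criterion, *config.extra_criteria):
            frame[f"ao_{crit.lower()}"] = classify_abdominal_obesity(
                frame["waist_cm"].to_numpy(dtype=float),
                frame["sex"].to_numpy(),
                CUTOFFS[crit],
            )
        outcome_col = f"ao_{config.criterion.lower()}"
        dataset = SurveyDataset(frame, dataset.covariates)

        stage = "descriptives"
        char_rows = []
        for cov in dataset.covariates:
            shares = (
                dataset.frame.groupby(["sex", cov], observed=True)["weight"].sum()
                / dataset.frame.groupby("sex", observed=True)["weight"].sum()
            )
            for (sex, level), share in shares.items():
                char_rows.append({"covariate": cov, "level": level, "sex": sex,
                                  "weighted_share": float(share)})
        emit_csv("characteristics.csv", pd.DataFrame(char_rows))

        prev_tables = []
        for crit in (config.criterion, *config.extra_criteria):
            col = f"ao_{crit.lower()}"
            for by in ([], *[[c] for c in dataset.covariates]):
                tab = weighted_prevalence(dataset, col, by=["sex"] + by)
                tab.insert(0, "criterion", crit)
                tab.insert(1, "stratifier", by[0] if by else "overall")
                if by:
                    tab = tab.rename(columns={by[0]: "level"})
                else:
                    tab["level"] = "all"
                prev_tables.append(tab)
        emit_csv("prevalence_by_group.csv", pd.concat(prev_tables, ignore_index=True))
        emit_csv("waist_means.csv", weighted_mean_se(dataset, "waist_cm", by=["sex"]))

        stage = "age_standardization"
        std = adult_standard()
        std_rows = []
        for sex, sub in _sex_groups(dataset):
            sub_bands = age_band_column(sub.frame["age_years"].to_numpy())
            w = sub.frame["weight"].to_numpy(dtype=float)
            y = sub.frame[outcome_col].to_numpy(dtype=float)
            band_prev = {}
            for band in std.bands:
                m = (sub_bands == band).to_numpy()
                if m.any():
                    band_prev[band] = float(np.sum(w[m] * y[m]) / np.sum(w[m]))
            crude = float(np.sum(w * y) / np.sum(w))
            if set(std.bands).issubset(band_prev):
                standardized = age_standardize(band_prev, std)
            else:
                standardized = float("nan")
            std_rows.append({"sex": sex, "crude_prevalence": crude,
                             "age_standardized_prevalence": standardized})
        emit_csv("prevalence_standardized.csv", pd.DataFrame(std_rows))

        stage = "concentration"
        index_rows, curves, decomp_results = [], {}, {}
        pooled_rank = fractional_rank(
            dataset.frame["wealth_score"].to_numpy(dtype=float),
            dataset.frame["weight"].to_numpy(dtype=float),
        )
        for sex, sub in _sex_groups(dataset):
            f = sub.frame
            w = f["weight"].to_numpy(dtype=float)
            y = f[outcome_col].to_numpy(dtype=float)
            if config.rank_scope == "within-sex":
                rank = fractional_rank(f["wealth_score"].to_numpy(dtype=float), w)
            else:
                rank = pooled_rank[(dataset.frame["sex"] == sex).to_numpy()]
            psu = f["psu"].to_numpy() if f["psu"].notna().all() else None
            ranked = RankedOutcome.from_arrays(
                y, weights=w, rank=rank, bounds=(0.0, 1.0), psu=psu,
            )
            se_method = config.se_method
            if se_method == "cluster_robust" and psu is None:
                se_method = "convenient_regression"
            ci = concentration_index(ranked, se_method=se_method)
            eci = erreygers_index(ranked, se_method=se_method)
            index_rows.append({
                "sex": sex, "n": ranked.n, "mu": ranked.mu,
                "ci": ci.value, "ci_se": ci.se,
                "eci": eci.value, "eci_se": eci.se, "se_method": se_method,
            })
            curve = concentration_curve(ranked, n_points=201)
            curves[sex] = emit_csv(
                f"curve_{sex}.csv",
                pd.DataFrame({"cum_population": curve.x, "cum_outcome": curve.y}),
            )

            stage = f"decomposition[{sex}]"
            covariates = config.covariates or list(dataset.covariates)
            result = decompose_eci(
                sub, outcome_col, covariates,
                references=config.references or None, rank=rank, weights=w,
            )
            decomp_results[sex] = result
            table = result.to_frame()
            table.loc[len(table)] = {
                "variable": "Residual", "level": "", "elasticity": np.nan,
                "ci_k": np.nan, "contribution": result.residual,
                "pct": 100.0 * result.residual / result.total_eci
                if result.total_eci else np.nan,
            }
            table.loc[len(table)] = {
                "variable": "Total", "level": "", "elasticity": np.nan,
                "ci_k": np.nan, "contribution": result.total_eci, "pct": 100.0,
            }
            emit_csv(f"decomposition_{sex}.csv", table)
            stage = "concentration"
        emit_csv("concentration_indices.csv", pd.DataFrame(index_rows))

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "n_records": int(dataset.n),
            "drop_counts": drops,
            "exclusion_counts": dict(exclusions),
            "criterion": config.criterion,
            "rank_scope": config.rank_scope,
            "weight_policy": config.weight_policy,
            "outputs": sorted(p.name for p in written),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        exc.args = (f"stage {stage!r} failed: {exc}",)
        raise

    return {
        "out_dir": out_dir,
        "dataset": dataset,
        "indices": pd.DataFrame(index_rows),
        "decomposition": decomp_results,
        "manifest": manifest,
        "outputs": written,
    }
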