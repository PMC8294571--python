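import numpy as np
import pandas as pd
import pytest

from ineqdecomp.survey_data import SurveyDataset


def build_dataset(
    wealth,
    weight=None,
    sex=None,
    age=None,
    waist=None,
    year="y0",
    covariates=None,
    **extra_columns,
) -> SurveyDataset:
    """Construct a SurveyDataset from plain arrays for tests."""
    n = len(wealth)
    frame = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "year": year,
            "sex": sex if sex is not None else ["female"] * n,
            "age_years": age if age is not None else [40.0] * n,
            "waist_cm": waist if waist is not None else [90.0] * n,
            "wealth_score": np.asarray(wealth, dtype=float),
            "weight": np.asarray(weight if weight is not None else np.ones(n), dtype=float),
            "psu": pd.NA,
            "stratum": pd.NA,
            "pregnant": False,
        }
    )
    schema = {}
    for name, values in (covariates or {}).items():
        levels = sorted(set(values))
        frame[name] = pd.Categorical(values, categories=levels, ordered=True)
        schema[name] = levels
    for name, values in extra_columns.items():
        frame[name] = values
    return SurveyDataset(frame, schema)


@pytest.fixture
def make_dataset():
    return build_dataset
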