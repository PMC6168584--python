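import numpy as np
import pandas as pd
import pytest

from deltanet.io import MeasurementTable
from deltanet.synthetic import generate_cohort, preset


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small generated cohort shared by read-only tests."""
    table, choices, truth = generate_cohort(preset("tiny", seed=7, n_participants=80))
    return table, choices, truth


@pytest.fixture()
def simple_table():
    """Three participants, two biomarkers, hand-written dates."""
    measurements = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "biomarker": ["LDL", "LDL", "LDL", "LDL", "HDL", "HDL"],
            "value": [120.0, 110.0, 150.0, 160.0, 50.0, 55.0],
            "draw_date": [
                "2016-01-01", "2016-04-01",
                "2016-02-01", "2016-05-01",
                "2016-03-01", "2016-06-01",
            ],
        }
    )
    participants = pd.DataFrame(
        {
            "participant_id": ["p1", "p2", "p3"],
            "sex": ["male", "female", "male"],
            "age": [40, 35, 50],
        }
    )
    return MeasurementTable(measurements, participants)


def make_pairs(**columns) -> pd.DataFrame:
    """Build a pairs frame from column lists, deriving delta and dummy dates."""
    df = pd.DataFrame(columns)
    n = len(df)
    defaults = {
        "participant_id": [f"p{i}" for i in range(n)],
        "biomarker": ["X"] * n,
        "baseline_date": pd.to_datetime(["2016-01-15"] * n),
        "followup_date": pd.to_datetime(["2016-11-15"] * n),
    }
    for col, vals in defaults.items():
        if col not in df:
            df[col] = vals
    df["baseline_date"] = pd.to_datetime(df["baseline_date"])
    df["followup_date"] = pd.to_datetime(df["followup_date"])
    df["delta"] = df["followup_value"] - df["baseline_value"]
    return df
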