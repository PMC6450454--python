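import datetime as dt

import pandas as pd
import pytest

from acsc_equity import ConditionConfig


@pytest.fixture
def config() -> ConditionConfig:
    """Asthma over calendar 2016 at one facility, default 3x4x2 grid."""
    return ConditionConfig(
        condition="asthma",
        code_prefixes=("J45",),
        window_start=dt.date(2016, 1, 1),
        window_end=dt.date(2017, 1, 1),
        facility_id="HOSP-A",
    )


def encounter_row(
    patient_id="P1",
    encounter_id="E1",
    date="2016-06-15",
    facility_id="HOSP-A",
    diagnosis_code="J45.901",
    tract_id="T001",
    age=30,
    gender="F",
    race_ethnicity="AA",
):
    return dict(
        patient_id=patient_id,
        encounter_id=encounter_id,
        date=date,
        facility_id=facility_id,
        diagnosis_code=diagnosis_code,
        tract_id=tract_id,
        age=age,
        gender=gender,
        race_ethnicity=race_ethnicity,
    )


def encounters_frame(rows):
    """Validated-shape encounter frame (as read_encounters would return)."""
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    df["age"] = df["age"].astype(int)
    return df


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, rows) -> str:
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return str(path)

    return _write


@pytest.fixture
def basic_prevalence():
    """Overall-only prevalence table for asthma."""
    return pd.DataFrame(
        [
            {
                "condition": "asthma",
                "age_band": "",
                "race": "",
                "gender": "",
                "prevalence": 0.1,
                "source": "test",
            }
        ]
    )
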