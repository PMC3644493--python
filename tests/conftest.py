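import datetime as dt

import pandas as pd
import pytest

from lbpclaims import StudyConfig
from lbpclaims.io import CLAIMS_COLUMNS


@pytest.fixture
def cfg() -> StudyConfig:
    return StudyConfig()


def make_claims(rows):
    """Build a claims frame from (patient_id, sex, birth_year, date, icd9) rows."""
    df = pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
    df["service_date"] = pd.to_datetime(df["service_date"])
    df["birth_year"] = df["birth_year"].astype(int)
    return df


@pytest.fixture
def claims_factory():
    return make_claims
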