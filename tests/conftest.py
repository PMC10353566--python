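import datetime as dt

import pytest

from repaudit import HarmonizationPolicy, PatientRecord


@pytest.fixture
def policy():
    return HarmonizationPolicy()


def make_record(
    patient_id="P1",
    age=40,
    sex="Female",
    race="White",
    ethnicity="Non-Hispanic",
    covid_status="positive",
    batch_date=dt.date(2021, 1, 1),
    site_id="S01",
):
    return PatientRecord(
        patient_id=patient_id,
        age_at_index=age,
        sex=sex,
        race=race,
        ethnicity=ethnicity,
        covid_status=covid_status,
        batch_date=batch_date,
        site_id=site_id,
    )


@pytest.fixture
def record_factory():
    return make_record
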