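import datetime as dt

import pytest

from neoqc import (
    GestationalAge,
    InfantRecord,
    NOT_APPLICABLE,
    default_config,
    default_dictionary,
    generate_cohort,
)


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def cohort():
    """Default nine-unit, six-year synthetic cohort (shared, read-only)."""
    records, meta = generate_cohort(default_config(seed=20090101))
    return records


def make_record(
    record_id="r1",
    unit_id="A",
    birth_date=dt.date(2010, 6, 15),
    ga=(27, 0),
    birth_weight=900.0,
    sex="male",
    multiple_birth=False,
    delivery_room_death=False,
    items=None,
):
    """Hand-built record with sane defaults for unit tests."""
    return InfantRecord(
        record_id=record_id,
        unit_id=unit_id,
        birth_date=birth_date,
        gestational_age=GestationalAge(*ga) if ga else None,
        birth_weight=birth_weight,
        sex=sex,
        multiple_birth=multiple_birth,
        delivery_room_death=delivery_room_death,
        items=dict(items or {}),
    )
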