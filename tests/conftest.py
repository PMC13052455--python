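import datetime as dt

import pytest

from skatemark.curation import Thresholds
from skatemark.records import (
    CaptureRecord,
    EventType,
    PortTable,
    Programme,
    Sex,
)
from skatemark.synthetic import SyntheticConfig, generate_coastline


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def circle_geo():
    """Deterministic circular island with 4 sectors and 8 ports."""
    cfg = SyntheticConfig(seed=7, coastline="circle_island", n_sectors=4)
    return generate_coastline(cfg)


@pytest.fixture(scope="session")
def port_table():
    return PortTable.from_rows(
        [("Union Hall", -9.13, 51.56), ("Clew Bay", -9.65, 53.85)]
    )


def make_record(
    record_id="r0",
    programme=Programme.IFI,
    tagger_id="T-1",
    tag_ids=(),
    event_type=EventType.CAPTURE,
    date=dt.date(2000, 7, 1),
    sex=Sex.U,
    tl=None,
    lon=None,
    lat=None,
    port_name=None,
    **kw,
):
    return CaptureRecord(
        record_id=record_id,
        programme=programme,
        tagger_id=tagger_id,
        tag_ids=tuple(tag_ids),
        event_type=event_type,
        date=date,
        sex=sex,
        total_length_cm=tl,
        lon=lon,
        lat=lat,
        port_name=port_name,
        **kw,
    )
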