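"""Reading, unit conversion, location resolution and round-trip of records."""

import datetime as dt
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skatemark.records import (
    CaptureRecord,
    EventType,
    LocationProvenance,
    PortTable,
    Programme,
    Sex,
    read_canonical,
    read_capture_records,
    resolve_location,
    write_records,
)

IFI_HEADER = (
    "tagger_id,tag_id_1,tag_id_2,tag_id_3,tag_type,event_type,date,sex,"
    "length_value,length_unit,wingspan_cm,weight_kg,lon,lat,port_name,comments\n"
)


def write_ifi(tmp_path: Path, rows: list[str]) -> Path:
    p = tmp_path / "ifi.csv"
    p.write_text(IFI_HEADER + "".join(r + "\n" for r in rows))
    return p


class TestReadIFI:
    def test_inch_lengths_convert_at_254(self, tmp_path, port_table):
        p = write_ifi(tmp_path, ["T1,A1,,,dart,capture,01/07/2000,F,63,in,,,-9.0,51.5,,"])
        (rec,) = read_capture_records(p, Programme.IFI, port_table)
        assert rec.total_length_cm == pytest.approx(160.02, abs=1e-9)

    def test_cm_lengths_never_rescaled(self, tmp_path, port_table):
        p = write_ifi(tmp_path, [
            "T1,A1,,,dart,capture,01/07/2000,F,170,cm,,,-9.0,51.5,,",
            "T1,A2,,,dart,capture,01/07/2000,F,170,,,,-9.0,51.5,,",  # absent flag = cm
        ])
        recs = read_capture_records(p, Programme.IFI, port_table)
        assert [r.total_length_cm for r in recs] == [170.0, 170.0]

    def test_header_only_file_gives_empty_list(self, tmp_path, port_table):
        p = write_ifi(tmp_path, [])
        assert read_capture_records(p, Programme.IFI, port_table) == []

    def test_port_in_standard_list_fills_coordinates(self, tmp_path, port_table):
        p = write_ifi(tmp_path, ["T1,A1,,,dart,capture,01/07/2000,F,170,cm,,,,,Union Hall,"])
        (rec,) = read_capture_records(p, Programme.IFI, port_table)
        assert (rec.lon, rec.lat) == port_table.lookup("Union Hall")
        assert rec.location_provenance is LocationProvenance.PORT_PROXY

    def test_malformed_fields_keep_record_with_warnings(self, tmp_path, port_table):
        p = write_ifi(tmp_path, ["T1,A1,,,dart,capture,not-a-date,X,tall,cm,,,-9.0,51.5,,"])
        (rec,) = read_capture_records(p, Programme.IFI, port_table)
        assert rec.date is None
        assert rec.sex is Sex.U
        assert rec.total_length_cm is None
        assert any("date" in w for w in rec.warnings)

    def test_no_row_silently_dropped(self, tmp_path, port_table):
        rows = ["T1,A1,,,dart,capture,01/07/2000,F,170,cm,,,,,Nowhere Port,"]
        recs = read_capture_records(write_ifi(tmp_path, rows), Programme.IFI, port_table)
        assert len(recs) == 1
        assert recs[0].unresolvable

    def test_day_first_dates(self, tmp_path, port_table):
        p = write_ifi(tmp_path, ["T1,A1,,,dart,capture,02/03/1999,F,170,cm,,,-9.0,51.5,,"])
        (rec,) = read_capture_records(p, Programme.IFI, port_table)
        assert rec.date == dt.date(1999, 3, 2)


class TestResolveLocation:
    def test_exact_coordinates_untouched(self, port_table):
        rec = CaptureRecord("r", Programme.IFI, "t", lon=-9.5, lat=51.2)
        out = resolve_location(rec, port_table)
        assert (out.lon, out.lat) == (-9.5, 51.2)
        assert out.location_provenance is LocationProvenance.EXACT

    def test_port_proxy(self, port_table):
        rec = CaptureRecord("r", Programme.IFI, "t", port_name="Clew Bay")
        out = resolve_location(rec, port_table)
        assert (out.lon, out.lat) == port_table.lookup("Clew Bay")
        assert out.location_provenance is LocationProvenance.PORT_PROXY

    def test_idempotent_and_never_overwrites(self, port_table):
        rec = CaptureRecord("r", Programme.IFI, "t", port_name="Clew Bay")
        once = resolve_location(rec, port_table)
        twice = resolve_location(once, port_table)
        assert once == twice

    def test_unknown_port_flags_unresolvable(self, port_table):
        rec = CaptureRecord("r", Programme.IFI, "t", port_name="Atlantis")
        assert resolve_location(rec, port_table).unresolvable


records_strategy = st.builds(
    CaptureRecord,
    record_id=st.text(alphabet="abcdef0123456789", min_size=1, max_size=8),
    programme=st.sampled_from(list(Programme)),
    tagger_id=st.text(alphabet="T0123456789", min_size=1, max_size=6),
    tag_ids=st.lists(
        st.text(alphabet="ABC123", min_size=1, max_size=5), max_size=3, unique=True
    ).map(tuple),
    event_type=st.just(EventType.CAPTURE),
    date=st.one_of(st.none(), st.dates(dt.date(1958, 1, 1), dt.date(2022, 12, 31))),
    sex=st.sampled_from(list(Sex)),
    total_length_cm=st.one_of(st.none(), st.floats(50, 260, allow_nan=False)),
    wingspan_cm=st.one_of(st.none(), st.floats(10, 250, allow_nan=False)),
    weight_kg=st.one_of(st.none(), st.floats(0.1, 120, allow_nan=False)),
    lon=st.floats(-179.9, 179.9, allow_nan=False),
    lat=st.floats(-89.9, 89.9, allow_nan=False),
    location_provenance=st.sampled_from(list(LocationProvenance)),
    port_name=st.one_of(st.none(), st.text(alphabet="Port aZ,9", min_size=1, max_size=10)),
    comments=st.text(alphabet="abc ,;\"'", max_size=15),
)


class TestRoundTrip:
    @settings(max_examples=60, deadline=None)
    @given(st.lists(records_strategy, max_size=6))
    def test_write_read_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "records.csv"
        write_records(records, path)
        assert read_canonical(path) == records

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_records([], path)
        assert path.read_text().count("\n") == 1
        assert read_canonical(path) == []

    def test_missing_values_are_blank_cells(self, tmp_path):
        rec = CaptureRecord(
            "r0", Programme.ISFC, "c1", sex=Sex.U, lon=-9.0, lat=51.0,
            location_provenance=LocationProvenance.EXACT,
        )
        path = tmp_path / "na.csv"
        write_records([rec], path)
        data_row = path.read_text().splitlines()[1]
        assert "NA" not in data_row and "nan" not in data_row
        (back,) = read_canonical(path)
        assert back.weight_kg is None and back.total_length_cm is None
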