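"""Reading, validation and normalisation of angler capture records.

Two source dialects are supported, emulating the field layouts of the two
Irish community-science programmes: the IFI marine sportfish tagging logbooks
(tag ids, a length unit flag because some anglers reported inches) and the
ISFC specimen-claim forms (no tags, lengths always in cm).  Records are
normalised into :class:`CaptureRecord` with lengths in cm, ISO dates, WGS84
lon/lat and an explicit provenance flag saying where the coordinates came
from (exact position, a port the angler chose as a proxy, or a standard
coordinate list applied during digitisation).

Missing values are ``None`` in memory and empty cells on disk; no sentinel
numbers anywhere.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

INCH_TO_CM = 2.54


class Programme(str, Enum):
    IFI = "IFI"
    ISFC = "ISFC"


class EventType(str, Enum):
    CAPTURE = "capture"
    RECAPTURE = "recapture"


class Sex(str, Enum):
    M = "M"
    F = "F"
    U = "U"


class LocationProvenance(str, Enum):
    EXACT = "exact"
    PORT_PROXY = "port_proxy"
    STANDARD_LIST = "standard_list"


@dataclass
class CaptureRecord:
    """One digitised capture or recapture event."""

    record_id: str
    programme: Programme
    tagger_id: str
    tag_ids: tuple[str, ...] = ()
    event_type: EventType = EventType.CAPTURE
    date: Optional[Date] = None
    sex: Sex = Sex.U
    total_length_cm: Optional[float] = None
    wingspan_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    lon: Optional[float] = None
    lat: Optional[float] = None
    location_provenance: Optional[LocationProvenance] = None
    port_name: Optional[str] = None
    comments: str = ""
    unresolvable: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def has_coordinates(self) -> bool:
        return self.lon is not None and self.lat is not None

    def validate(self) -> None:
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"{self.record_id}: latitude {self.lat} outside [-90, 90]")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"{self.record_id}: longitude {self.lon} outside [-180, 180]")
        if self.total_length_cm is not None and self.total_length_cm <= 0:
            raise ValueError(f"{self.record_id}: non-positive total length")
        if self.event_type is EventType.RECAPTURE and not self.tag_ids:
            raise ValueError(f"{self.record_id}: recapture without a tag id")


@dataclass
class PortTable:
    """Standard coordinate list mapping port names to positions.

    Each programme maintained its own list; the two need not agree, so one
    table is built per programme.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, float, float]]) -> "PortTable":
        table: dict[str, tuple[float, float]] = {}
        for name, lon, lat in rows:
            if name in table:
                raise ValueError(f"duplicate port name {name!r}")
            table[name] = (float(lon), float(lat))
        return cls(table)

    @classmethod
    def read(cls, path: str | Path) -> "PortTable":
        path = Path(path)
        if path.suffix.lower() in {".geojson", ".json"}:
            import json

            data = json.loads(path.read_text())
            rows = []
            for feat in data["features"]:
                lon, lat = feat["geometry"]["coordinates"][:2]
                rows.append((feat["properties"]["port_name"], lon, lat))
            return cls.from_rows(rows)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            return cls.from_rows(
                (row["port_name"], float(row["lon"]), float(row["lat"])) for row in reader
            )

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["port_name", "lon", "lat"])
            for name, (lon, lat) in self.entries.items():
                writer.writerow([name, repr(lon), repr(lat)])

    def lookup(self, name: str) -> Optional[tuple[float, float]]:
        return self.entries.get(name)


IFI_COLUMNS = [
    "tagger_id", "tag_id_1", "tag_id_2", "tag_id_3", "tag_type", "event_type",
    "date", "sex", "length_value", "length_unit", "wingspan_cm", "weight_kg",
    "lon", "lat", "port_name", "comments",
]
ISFC_COLUMNS = [
    "claimant_id", "skipper_id", "date", "sex", "total_length_cm", "wingspan_cm",
    "weight_kg", "port_name", "lon", "lat", "platform", "comments",
]
CANONICAL_COLUMNS = [
    "record_id", "programme", "tagger_id", "tag_ids", "event_type", "date", "sex",
    "total_length_cm", "wingspan_cm", "weight_kg", "lon", "lat",
    "location_provenance", "port_name", "comments",
]

# source logbooks/forms use day-first dates; the canonical dialect is ISO-8601
DIALECT_DATE_FORMAT = {Programme.IFI: "%d/%m/%Y", Programme.ISFC: "%d/%m/%Y"}


def _blank(value: Optional[str]) -> bool:
    return value is None or value.strip() == ""


def _parse_float(token: Optional[str]) -> Optional[float]:
    if _blank(token):
        return None
    try:
        value = float(token)
    except ValueError:
        return None
    if math.isnan(value):
        return None
    return value


def _parse_sex(token: Optional[str]) -> Sex:
    if _blank(token):
        return Sex.U
    t = token.strip().upper()
    if t in {"M", "MALE"}:
        return Sex.M
    if t in {"F", "FEMALE"}:
        return Sex.F
    return Sex.U


def _parse_date(token: Optional[str], fmt: str) -> Optional[Date]:
    if _blank(token):
        return None
    for f in (fmt, "%Y-%m-%d"):
        try:
            return datetime.strptime(token.strip(), f).date()
        except ValueError:
            continue
    return None


def read_capture_records(
    path: str | Path,
    dialect: Programme,
    port_table: PortTable,
    study_span: Optional[tuple[int, int]] = None,
) -> list[CaptureRecord]:
    """Read one programme's CSV into validated, location-resolved records.

    No row is silently dropped: rows with unparseable dates or lengths keep
    the record with the field absent and a warning attached; rows with no
    coordinates and no resolvable port are emitted unresolved with a warning.
    IFI lengths flagged ``in`` are converted to cm at exactly 2.54 cm/inch.
    """
    path = Path(path)
    fmt = DIALECT_DATE_FORMAT[dialect]
    records: list[CaptureRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            rid = f"{dialect.value}-{i:06d}"
            warnings: list[str] = []
            if dialect is Programme.IFI:
                tags = tuple(
                    row[c].strip()
                    for c in ("tag_id_1", "tag_id_2", "tag_id_3")
                    if not _blank(row.get(c))
                )
                ev_token = (row.get("event_type") or "").strip().lower()
                event_type = (
                    EventType.RECAPTURE if ev_token == "recapture" else EventType.CAPTURE
                )
                length = _parse_float(row.get("length_value"))
                if length is None and not _blank(row.get("length_value")):
                    warnings.append("unparseable length")
                unit = (row.get("length_unit") or "").strip().lower()
                if length is not None and unit == "in":
                    length = length * INCH_TO_CM
                tagger = (row.get("tagger_id") or "").strip()
            else:
                tags = ()
                event_type = EventType.CAPTURE
                length = _parse_float(row.get("total_length_cm"))
                if length is None and not _blank(row.get("total_length_cm")):
                    warnings.append("unparseable length")
                tagger = (row.get("claimant_id") or "").strip()
            when = _parse_date(row.get("date"), fmt)
            if when is None and not _blank(row.get("date")):
                warnings.append("malformed date")
            if when is not None and study_span is not None:
                if not study_span[0] <= when.year <= study_span[1]:
                    warnings.append(f"date {when} outside study span {study_span}")
            record = CaptureRecord(
                record_id=rid,
                programme=dialect,
                tagger_id=tagger,
                tag_ids=tags,
                event_type=event_type,
                date=when,
                sex=_parse_sex(row.get("sex")),
                total_length_cm=length,
                wingspan_cm=_parse_float(row.get("wingspan_cm")),
                weight_kg=_parse_float(row.get("weight_kg")),
                lon=_parse_float(row.get("lon")),
                lat=_parse_float(row.get("lat")),
                port_name=None if _blank(row.get("port_name")) else row["port_name"].strip(),
                comments=(row.get("comments") or "").strip(),
                warnings=tuple(warnings),
            )
            record = resolve_location(record, port_table)
            record.validate()
            if record.warnings:
                logger.warning("%s: %s", record.record_id, "; ".join(record.warnings))
            records.append(record)
    n_unresolved = sum(r.unresolvable for r in records)
    if n_unresolved:
        logger.warning("%d record(s) with unresolvable locations", n_unresolved)
    return records


def resolve_location(record: CaptureRecord, port_table: PortTable) -> CaptureRecord:
    """Fill coordinates from the port table when the angler gave only a port.

    Idempotent; exact coordinates are never overwritten.  Provenance: `exact`
    when the angler supplied a position, `port_proxy` when they deliberately
    named a port instead, `standard_list` when digitisation assigned one.
    """
    if record.has_coordinates:
        if record.location_provenance is None:
            return replace(record, location_provenance=LocationProvenance.EXACT)
        return record
    if record.port_name is not None:
        coords = port_table.lookup(record.port_name)
        if coords is not None:
            return replace(
                record,
                lon=coords[0],
                lat=coords[1],
                location_provenance=LocationProvenance.PORT_PROXY,
            )
    return replace(
        record,
        unresolvable=True,
        warnings=record.warnings + ("no coordinates and no resolvable port",),
    )


def _fmt_optional(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_records(records: Sequence[CaptureRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect (ISO dates, cm, lon/lat).

    Round-trip contract: ``read_canonical(write_records(x)) == x`` on every
    field; absent values are empty cells.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.programme.value,
                    r.tagger_id,
                    ";".join(r.tag_ids),
                    r.event_type.value,
                    r.date.isoformat() if r.date else "",
                    r.sex.value,
                    _fmt_optional(r.total_length_cm),
                    _fmt_optional(r.wingspan_cm),
                    _fmt_optional(r.weight_kg),
                    _fmt_optional(r.lon),
                    _fmt_optional(r.lat),
                    r.location_provenance.value if r.location_provenance else "",
                    r.port_name or "",
                    r.comments,
                ]
            )


def read_canonical(path: str | Path) -> list[CaptureRecord]:
    """Read the canonical dialect written by :func:`write_records`."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                CaptureRecord(
                    record_id=row["record_id"],
                    programme=Programme(row["programme"]),
                    tagger_id=row["tagger_id"],
                    tag_ids=tuple(t for t in row["tag_ids"].split(";") if t),
                    event_type=EventType(row["event_type"]),
                    date=Date.fromisoformat(row["date"]) if row["date"] else None,
                    sex=Sex(row["sex"]),
                    total_length_cm=_parse_float(row["total_length_cm"]),
                    wingspan_cm=_parse_float(row["wingspan_cm"]),
                    weight_kg=_parse_float(row["weight_kg"]),
                    lon=_parse_float(row["lon"]),
                    lat=_parse_float(row["lat"]),
                    location_provenance=(
                        LocationProvenance(row["location_provenance"])
                        if row["location_provenance"]
                        else None
                    ),
                    port_name=row["port_name"] or None,
                    comments=row["comments"],
                )
            )
    return records
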