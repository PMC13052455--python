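"""Linking capture records into per-individual histories.

Individuals carry one to three conventional tags; records are linked by
transitive closure over shared tag identifiers (a record listing tags {A, B}
joins records listing {A} and records listing {B}), which supports
multi-tagged animals.  Specimen claims without tags become singleton
histories.  Days at liberty are whole-day differences between successive
dated events; undated events are kept for spatial counts but excluded from
intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .curation import Thresholds, reconcile_sex
from .records import CaptureRecord, Sex

logger = logging.getLogger(__name__)


@dataclass
class LibertyInterval:
    from_index: int
    to_index: int
    days: int


@dataclass
class CaptureHistory:
    individual_id: str
    events: list[CaptureRecord]
    reconciled_sex: Sex = Sex.U
    tag_id_set: frozenset[str] = frozenset()
    liberty_intervals: list[LibertyInterval] = field(default_factory=list)
    cumulative_days: int = 0

    @property
    def n_recaptures(self) -> int:
        return max(0, len(self.events) - 1)

    def dated_events(self) -> list[CaptureRecord]:
        return [e for e in self.events if e.date is not None]


@dataclass
class LinkageConflict:
    individual_id: str
    record_ids: tuple[str, str]
    reason: str


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice keeps linkage order-independent
            if str(ra) > str(rb):
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_histories(
    records: Sequence[CaptureRecord],
    tl_conflict_cm: float = 30.0,
) -> tuple[list[CaptureHistory], list[LinkageConflict]]:
    """Group records into histories by transitive tag-sharing.

    Returns histories plus a conflict report: two same-tag records on the same
    date whose TLs differ by more than ``tl_conflict_cm`` are flagged (likely
    tag transcription errors) but remain linked.  Linkage is independent of
    input order; every record lands in exactly one history.
    """
    uf = _UnionFind()
    tag_owner: dict[str, str] = {}
    for rec in records:
        uf.find(("rec", rec.record_id))
        for tag in rec.tag_ids:
            if tag in tag_owner:
                uf.union(("rec", rec.record_id), ("rec", tag_owner[tag]))
            else:
                tag_owner[tag] = rec.record_id
            uf.union(("rec", rec.record_id), ("rec", tag_owner[tag]))
    groups: dict = {}
    by_id = {r.record_id: r for r in records}
    for rec in records:
        root = uf.find(("rec", rec.record_id))
        groups.setdefault(root, []).append(rec.record_id)

    histories: list[CaptureHistory] = []
    conflicts: list[LinkageConflict] = []
    for k, (root, rec_ids) in enumerate(sorted(groups.items(), key=lambda kv: sorted(kv[1]))):
        evs = [by_id[rid] for rid in rec_ids]
        evs.sort(key=lambda e: (e.date is None, e.date or _MAX_DATE, e.record_id))
        hid = f"ind-{min(rec_ids)}"
        hist = CaptureHistory(
            individual_id=hid,
            events=evs,
            tag_id_set=frozenset(t for e in evs for t in e.tag_ids),
        )
        hist.reconciled_sex = reconcile_sex(hist)
        histories.append(hist)
        for i, a in enumerate(evs):
            for b in evs[i + 1:]:
                if (
                    a.date is not None and a.date == b.date
                    and a.total_length_cm is not None and b.total_length_cm is not None
                    and abs(a.total_length_cm - b.total_length_cm) > tl_conflict_cm
                ):
                    conflicts.append(
                        LinkageConflict(hid, (a.record_id, b.record_id),
                                        "same tag/date, incompatible TL")
                    )
    if conflicts:
        logger.warning("%d linkage conflict(s) flagged", len(conflicts))
    return histories, conflicts


import datetime as _dt  # noqa: E402

_MAX_DATE = _dt.date.max


def liberty_intervals(history: CaptureHistory, thresholds: Thresholds) -> CaptureHistory:
    """Fill in days-at-liberty intervals between successive dated events.

    A same-day recapture is a valid 0-day interval.  Cumulative days equals
    the sum of intervals (= last dated event minus first dated event).
    """
    dated = history.dated_events()
    intervals: list[LibertyInterval] = []
    for k in range(len(dated) - 1):
        days = (dated[k + 1].date - dated[k].date).days
        intervals.append(
            LibertyInterval(
                from_index=history.events.index(dated[k]),
                to_index=history.events.index(dated[k + 1]),
                days=days,
            )
        )
    history.liberty_intervals = intervals
    history.cumulative_days = sum(iv.days for iv in intervals)
    return history


def days_to_years(days: float, thresholds: Optional[Thresholds] = None) -> float:
    """Days -> years at 365.25 d/y, rounded half-up to 1 decimal."""
    per_year = (thresholds or Thresholds()).days_per_year
    from .summaries import round_half_up

    return round_half_up(days / per_year, 1)


def write_history_events_csv(histories: Sequence[CaptureHistory], path: str | Path) -> None:
    """One row per event, tagged with its individual id."""
    import csv

    from .records import CANONICAL_COLUMNS

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id"] + CANONICAL_COLUMNS)
        for h in histories:
            for e in h.events:
                writer.writerow([h.individual_id] + _canonical_row(e))


def _canonical_row(r: CaptureRecord) -> list[str]:
    from .records import _fmt_optional

    return [
        r.record_id, r.programme.value, r.tagger_id, ";".join(r.tag_ids),
        r.event_type.value, r.date.isoformat() if r.date else "", r.sex.value,
        _fmt_optional(r.total_length_cm), _fmt_optional(r.wingspan_cm),
        _fmt_optional(r.weight_kg), _fmt_optional(r.lon), _fmt_optional(r.lat),
        r.location_provenance.value if r.location_provenance else "",
        r.port_name or "", r.comments,
    ]


def write_history_summaries_jsonl(histories: Sequence[CaptureHistory], path: str | Path) -> None:
    """One JSON object per individual: sex, tags, event count, liberty days."""
    with open(path, "w") as fh:
        for h in histories:
            fh.write(
                json.dumps(
                    {
                        "individual_id": h.individual_id,
                        "sex": h.reconciled_sex.value,
                        "n_events": len(h.events),
                        "tags": sorted(h.tag_id_set),
                        "cumulative_days": h.cumulative_days,
                        "interval_days": [iv.days for iv in h.liberty_intervals],
                    }
                )
                + "\n"
            )
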