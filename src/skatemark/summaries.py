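"""Summary statistics over curated records, histories and dispersal results.

One rounding rule is used for every reported share: half-up at the printed
precision (integer percentages for shares, one decimal for year and km
means).  Each block records its own numerator and denominator so reported
rates are auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .curation import Maturity, Thresholds, classify_maturity
from .dispersal import DispersalResult
from .histories import CaptureHistory
from .records import CaptureRecord, Sex


def round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100*n/d rounded half-up to ``decimals``; errors on a zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def monthly_counts(
    records: Sequence[CaptureRecord],
    stratifier: str = "sex",
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """12-row month x stratum table of dated records.

    ``stratifier`` is ``"sex"`` (columns F, M, U) or ``"maturity"`` (mature,
    immature, unclassified).  Undated records are excluded from the table and
    counted in the frame's ``attrs["n_undated"]`` footnote.
    """
    thr = thresholds or Thresholds()
    dated = [r for r in records if r.date is not None]
    rows = []
    for r in dated:
        if stratifier == "sex":
            stratum = r.sex.value
        elif stratifier == "maturity":
            stratum = classify_maturity(r.sex, r.total_length_cm, thr)
        else:
            raise ValueError(f"unknown stratifier {stratifier!r}")
        rows.append({"month": r.date.month, "stratum": stratum})
    columns = (
        ["F", "M", "U"]
        if stratifier == "sex"
        else [Maturity.MATURE, Maturity.IMMATURE, Maturity.UNCLASSIFIED]
    )
    table = pd.DataFrame(0, index=range(1, 13), columns=columns)
    if rows:
        df = pd.DataFrame(rows)
        pivot = df.value_counts(["month", "stratum"]).unstack(fill_value=0)
        for col in pivot.columns:
            table.loc[pivot.index, col] = pivot[col]
    table.index.name = "month"
    table.attrs["n_undated"] = len(records) - len(dated)
    return table


def season_share_pct(table: pd.DataFrame, months: Sequence[int] = range(6, 11)) -> float:
    """Share (%) of dated records falling in the given months (default Jun-Oct)."""
    total = int(table.values.sum())
    in_season = int(table.loc[list(months)].values.sum())
    return percentage(in_season, total)


@dataclass
class RecaptureBlock:
    n_individuals: int
    n_recaptured: int
    n_recapture_events: int
    recapture_rate_pct: float
    events_per_recaptured: dict[int, int]
    liberty_bins: dict[str, int]
    liberty_mean_days: Optional[float]
    liberty_sd_days: Optional[float]
    liberty_mean_years: Optional[float]
    by_sex_mean_sd_days: dict[str, tuple[Optional[float], Optional[float]]]
    pct_individuals_near: Optional[float]
    pct_events_same_port: Optional[float]
    dispersal_by_sex_km: dict[str, tuple[Optional[float], Optional[float]]]
    max_dispersal_km: Optional[float]


def _mean_sd(values: list[float], decimals: int = 1):
    if not values:
        return None, None
    s = pd.Series(values, dtype=float)
    sd = s.std(ddof=1) if len(s) > 1 else 0.0
    return round_half_up(float(s.mean()), decimals), round_half_up(float(sd), decimals)


def recapture_summary(
    histories: Sequence[CaptureHistory],
    dispersal: Sequence[DispersalResult],
    thresholds: Thresholds,
) -> RecaptureBlock:
    """Recapture-rate, time-at-liberty and dispersal block.

    Rate = 100 * recaptured individuals / unique individuals (the denominator
    is the individual count of the supplied histories and is reported
    alongside).  Liberty bins split intervals at 1 and 2 years (365.25 and
    730.5 days).  The share of individuals dispersing < near_dispersal_km
    uses each individual's maximum interval distance.
    """
    n_ind = len(histories)
    recaptured = [h for h in histories if h.n_recaptures > 0]
    intervals = [iv for h in histories for iv in h.liberty_intervals]
    events_per = {}
    for h in recaptured:
        events_per[h.n_recaptures] = events_per.get(h.n_recaptures, 0) + 1
    yr = thresholds.days_per_year
    bins = {
        "<1y": sum(1 for iv in intervals if iv.days < yr),
        "1-2y": sum(1 for iv in intervals if yr <= iv.days <= 2 * yr),
        ">2y": sum(1 for iv in intervals if iv.days > 2 * yr),
    }
    days = [float(iv.days) for iv in intervals]
    mean_d, sd_d = _mean_sd(days, 0)
    by_sex_days = {}
    for sex in (Sex.F, Sex.M, Sex.U):
        vals = [
            float(iv.days)
            for h in histories
            if h.reconciled_sex is sex
            for iv in h.liberty_intervals
        ]
        by_sex_days[sex.value] = _mean_sd(vals, 0)

    per_ind_max: dict[str, float] = {}
    per_sex_dist: dict[str, list[float]] = {"F": [], "M": [], "U": []}
    sex_of = {h.individual_id: h.reconciled_sex.value for h in histories}
    for res in dispersal:
        per_ind_max[res.individual_id] = max(
            per_ind_max.get(res.individual_id, 0.0), res.distance_km
        )
        per_sex_dist.setdefault(sex_of.get(res.individual_id, "U"), []).append(
            res.distance_km
        )
    n_near = sum(1 for d in per_ind_max.values() if d < thresholds.near_dispersal_km)
    n_same_port = sum(1 for r in dispersal if r.distance_km == 0.0)
    return RecaptureBlock(
        n_individuals=n_ind,
        n_recaptured=len(recaptured),
        n_recapture_events=len(intervals),
        recapture_rate_pct=percentage(len(recaptured), n_ind) if n_ind else 0.0,
        events_per_recaptured=dict(sorted(events_per.items())),
        liberty_bins=bins,
        liberty_mean_days=mean_d,
        liberty_sd_days=sd_d,
        liberty_mean_years=(
            round_half_up(sum(days) / len(days) / yr, 1) if days else None
        ),
        by_sex_mean_sd_days=by_sex_days,
        pct_individuals_near=(
            percentage(n_near, len(per_ind_max)) if per_ind_max else None
        ),
        pct_events_same_port=(
            percentage(n_same_port, len(dispersal)) if dispersal else None
        ),
        dispersal_by_sex_km={
            s: _mean_sd(v, 1) for s, v in per_sex_dist.items()
        },
        max_dispersal_km=(
            round_half_up(max(r.distance_km for r in dispersal), 1) if dispersal else None
        ),
    )


@dataclass
class EffortBlock:
    per_tagger: dict[str, int]
    top_share_pct: float
    top_decile_share_pct: float


def effort_concentration(records: Sequence[CaptureRecord]) -> EffortBlock:
    """Per-tagger record counts with top-contributor concentration shares."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.tagger_id] = counts.get(r.tagger_id, 0) + 1
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    total = sum(ordered.values())
    values = list(ordered.values())
    top = values[0] if values else 0
    n_decile = max(1, len(values) // 10)
    top_decile = sum(values[:n_decile])
    return EffortBlock(
        per_tagger=ordered,
        top_share_pct=percentage(top, total) if total else 0.0,
        top_decile_share_pct=percentage(top_decile, total) if total else 0.0,
    )


@dataclass
class SummaryReport:
    n_records: int
    n_by_programme: dict[str, int]
    n_by_sex: dict[str, int]
    maturity_block: dict[str, int]
    jun_oct_share_pct: Optional[float]
    monthly_by_sex: dict
    recapture: Optional[dict] = None
    effort: Optional[dict] = None
    sectors: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    def render_text(self) -> str:
        lines = [
            f"records: {self.n_records}",
            f"by programme: {self.n_by_programme}",
            f"by sex: {self.n_by_sex}",
            f"maturity: {self.maturity_block}",
            f"Jun-Oct share of dated records: {self.jun_oct_share_pct}%",
        ]
        if self.sectors:
            lines.append(f"records by coast sector: {self.sectors}")
        if self.recapture:
            r = self.recapture
            lines += [
                f"individuals: {r['n_individuals']}, recaptured: {r['n_recaptured']} "
                f"({r['recapture_rate_pct']}%), recapture events: {r['n_recapture_events']}",
                f"time at liberty: mean {r['liberty_mean_days']} d "
                f"(SD {r['liberty_sd_days']}), {r['liberty_mean_years']} y; bins {r['liberty_bins']}",
                f"dispersal: {r['pct_individuals_near']}% of individuals < 50 km, "
                f"{r['pct_events_same_port']}% of events same port, "
                f"max {r['max_dispersal_km']} km",
            ]
        if self.effort:
            lines.append(
                f"effort: top tagger {self.effort['top_share_pct']}% of records"
            )
        return "\n".join(lines)


def build_report(
    records: Sequence[CaptureRecord],
    thresholds: Thresholds,
    histories: Optional[Sequence[CaptureHistory]] = None,
    dispersal: Optional[Sequence[DispersalResult]] = None,
    sectors: Optional[dict[str, int]] = None,
) -> SummaryReport:
    by_prog: dict[str, int] = {}
    by_sex: dict[str, int] = {}
    maturity: dict[str, int] = {}
    for r in records:
        by_prog[r.programme.value] = by_prog.get(r.programme.value, 0) + 1
        by_sex[r.sex.value] = by_sex.get(r.sex.value, 0) + 1
        m = classify_maturity(r.sex, r.total_length_cm, thresholds)
        maturity[m] = maturity.get(m, 0) + 1
    table = monthly_counts(records, "sex", thresholds)
    dated_total = int(table.values.sum())
    rec_block = (
        asdict(recapture_summary(histories, dispersal or [], thresholds))
        if histories is not None
        else None
    )
    return SummaryReport(
        n_records=len(records),
        n_by_programme=by_prog,
        n_by_sex=by_sex,
        maturity_block=maturity,
        jun_oct_share_pct=season_share_pct(table) if dated_total else None,
        monthly_by_sex=table.to_dict(),
        recapture=rec_block,
        effort=asdict(effort_concentration(records)) if records else None,
        sectors=sectors or {},
    )
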