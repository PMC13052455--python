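"""End-to-end pipeline: simulate -> curate -> link -> grid -> dispersal -> report.

This is the programmatic counterpart of the CLI subcommands; each stage is a
thin call into the corresponding module so scripted analyses, the CLI and
tests all run exactly the same code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import curation, dispersal, hexgrid, histories, summaries, synthetic
from .curation import Thresholds
from .records import CaptureRecord, Programme

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    dataset: synthetic.SyntheticDataset
    merged: list[CaptureRecord]
    duplicate_report: list[curation.DuplicatePair]
    histories: list[histories.CaptureHistory]
    mr_histories: list[histories.CaptureHistory]
    grid: hexgrid.HexGrid
    cells: dict[tuple[str, str], list[hexgrid.CellStat]] = field(default_factory=dict)
    dispersal_results: list[dispersal.DispersalResult] = field(default_factory=list)
    network: Optional[dispersal.WaterNetwork] = None
    report: Optional[summaries.SummaryReport] = None
    recovery: Optional[synthetic.RecoveryMetrics] = None
    sector_counts: dict[str, int] = field(default_factory=dict)


def curate_and_link(
    ifi: Sequence[CaptureRecord],
    isfc: Sequence[CaptureRecord],
    thresholds: Thresholds,
):
    """Deduplicate across programmes, link by tags, apply the species filter."""
    merged, dup_report = curation.deduplicate_cross_programme(
        ifi, isfc, thresholds.dup_tl_tol_cm, thresholds.dup_coord_tol_km
    )
    merged = [r for r in merged if not r.unresolvable]
    hists, _conflicts = histories.build_histories(merged)
    hists = curation.apply_species_filter(hists, thresholds)
    for h in hists:
        histories.liberty_intervals(h, thresholds)
    return merged, dup_report, hists


def grid_and_classify(
    records: Sequence[CaptureRecord],
    extent_lonlat,
    thresholds: Thresholds,
    subsets: Sequence[str] = ("all", "mature"),
) -> tuple[hexgrid.HexGrid, dict[tuple[str, str], list[hexgrid.CellStat]]]:
    """Hex-bin records for each timeframe x subset and classify the cells."""
    grid = hexgrid.build_hex_grid(extent_lonlat, thresholds.hex_cell_area_km2)
    frames = hexgrid.stratify_timeframes(records, thresholds)
    out: dict[tuple[str, str], list[hexgrid.CellStat]] = {}
    for tf_name, tf_records in frames.items():
        for subset in subsets:
            sel = hexgrid.subset_records(tf_records, subset, thresholds)
            counts = hexgrid.count_points_in_cells(grid, sel)
            total = sum(counts.values())
            out[(tf_name, subset)] = hexgrid.classify_cells(
                counts, total, thresholds, timeframe=tf_name, subset=subset
            )
    return grid, out


def compute_dispersal(
    hists: Sequence[histories.CaptureHistory],
    land_lonlat,
    extent_lonlat,
    thresholds: Thresholds,
    projection,
    network: Optional[dispersal.WaterNetwork] = None,
) -> tuple[list[dispersal.DispersalResult], Optional[dispersal.WaterNetwork]]:
    """Dispersal per interval; the water network is built only when needed.

    The triangulated network is expensive at fine resolution, so it is
    constructed lazily the first time any individual's track crosses land.
    """
    results: list[dispersal.DispersalResult] = []
    multi = [h for h in hists if len(h.dated_events()) >= 2]
    needs_network = False
    for h in multi:
        dated = [e for e in h.dated_events() if e.has_coordinates]
        for k in range(len(dated) - 1):
            if dispersal.segment_crosses_land(
                (dated[k].lon, dated[k].lat),
                (dated[k + 1].lon, dated[k + 1].lat),
                land_lonlat,
                projection,
            ):
                needs_network = True
                break
        if needs_network:
            break
    if needs_network and network is None:
        logger.info("building water network (triangle area %.3g km^2)",
                    thresholds.triangle_area_km2)
        network = dispersal.build_water_network(
            extent_lonlat, land_lonlat, thresholds.triangle_area_km2, projection
        )
    for h in multi:
        results.extend(dispersal.dispersal_distances(h, land_lonlat, network, projection))
    return results, network


def run_synthetic_pipeline(
    cfg: synthetic.SyntheticConfig,
    thresholds: Optional[Thresholds] = None,
    with_sectors: bool = False,
) -> PipelineResult:
    """Generate a dataset and run every analysis stage over it."""
    thr = thresholds or Thresholds()
    ds = synthetic.generate_dataset(cfg)
    merged, dup_report, hists = curate_and_link(ds.ifi, ds.isfc, thr)
    kept = [e for h in hists for e in h.events]
    grid, cells = grid_and_classify(kept, ds.geography.extent, thr)
    mr_hists = [
        h for h in hists if any(e.programme is Programme.IFI for e in h.events)
    ]
    disp, net = compute_dispersal(
        mr_hists, ds.geography.land, ds.geography.extent, thr, ds.geography.projection
    )
    sector_counts: dict[str, int] = {}
    if with_sectors:
        for r in kept:
            if r.has_coordinates:
                s = curation.assign_coast_sector(
                    (r.lon, r.lat), ds.geography.sectors, ds.geography.land,
                    ds.geography.projection,
                )
                sector_counts[s] = sector_counts.get(s, 0) + 1
    report = summaries.build_report(kept, thr, mr_hists, disp, sector_counts)
    recovery = synthetic.evaluate_recovery(
        ds.truth, cells[("all", "all")], disp, grid, mr_hists
    )
    return PipelineResult(
        dataset=ds,
        merged=merged,
        duplicate_report=dup_report,
        histories=hists,
        mr_histories=mr_hists,
        grid=grid,
        cells=cells,
        dispersal_results=disp,
        network=net,
        report=report,
        recovery=recovery,
        sector_counts=sector_counts,
    )
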