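#!/usr/bin/env python
"""Hexagonal hotspot maps per timeframe and maturity subset.

Bins curated capture events into 50 km^2 equal-area hexagons and classifies
cells (>10% of events = hotspot, 5-10% = area of interest) for all records,
the older timeframe (<= 2006) and the recent one (>= 2007), for all events
and for mature-classified events.  Writes cell tables and GeoJSON under
results/hotspots/.
"""

import json
from pathlib import Path

import shapely.geometry as sg

from skatemark.curation import Thresholds
from skatemark.hexgrid import cells_to_csv, cells_to_geojson
from skatemark.pipeline import curate_and_link, grid_and_classify
from skatemark.records import PortTable, Programme, read_capture_records

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    out = ROOT / "hotspots"
    out.mkdir(parents=True, exist_ok=True)
    thr = Thresholds()
    ifi = read_capture_records(
        data / "ifi_records.csv", Programme.IFI, PortTable.read(data / "ifi_ports.csv")
    )
    isfc = read_capture_records(
        data / "isfc_records.csv", Programme.ISFC, PortTable.read(data / "isfc_ports.csv")
    )
    _, _, hists = curate_and_link(ifi, isfc, thr)
    kept = [e for h in hists for e in h.events]
    with open(data / "extent.geojson") as fh:
        extent = sg.shape(json.load(fh)["features"][0]["geometry"])
    grid, cells = grid_and_classify(kept, extent, thr)
    for (tf, subset), stats in cells.items():
        cells_to_csv(stats, out / f"cells_{tf}_{subset}.csv")
        cells_to_geojson(grid, stats, out / f"cells_{tf}_{subset}.geojson")
        n_hot = sum(1 for s in stats if s.cls == "hotspot")
        n_aoi = sum(1 for s in stats if s.cls == "aoi")
        total = sum(s.count for s in stats)
        print(f"{tf:>6} / {subset:<6}: {total:5d} events, "
              f"{n_hot} hotspot cell(s), {n_aoi} AOI cell(s)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
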