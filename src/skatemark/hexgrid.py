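"""Equal-area hexagonal binning and hotspot classification.

Capture positions carry port-level accuracy at best, so spatial analysis
aggregates them to a regular grid of 50 km^2 hexagons laid out in the shared
equal-area projection.  A cell holding more than 10% of the capture events
of a timeframe/subset is a hotspot; 5%-10% is an "area of interest"; the
rest is background.  Timeframes split the record set at a configurable year
(default 2006: records up to it are "older", later ones "recent").

Hexagons are flat-topped with circumradius R = sqrt(2A / (3*sqrt(3))); the
tiling is anchored at the lower-left corner of the projected extent so two
runs over the same extent produce identical cells.  Because the hexagons are
the Voronoi cells of their centres, points are assigned to the nearest
centre; near-ties resolve to the smallest cell id, giving each hexagon a
deterministic half-open boundary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping

from .curation import Maturity, Thresholds, classify_maturity
from .projection import LambertEqualArea, projection_for
from .records import CaptureRecord, Sex

logger = logging.getLogger(__name__)


def hex_circumradius_km(cell_area_km2: float) -> float:
    """Circumradius of a regular hexagon with the given area."""
    return math.sqrt(2.0 * cell_area_km2 / (3.0 * math.sqrt(3.0)))


@dataclass
class HexGrid:
    projection: LambertEqualArea
    cell_area_km2: float
    centres: np.ndarray  # (n, 2) projected km
    cell_ids: list[int]
    extent_proj: Polygon
    _tree: Optional[cKDTree] = field(default=None, repr=False)

    @property
    def circumradius_km(self) -> float:
        return hex_circumradius_km(self.cell_area_km2)

    def cell_polygon(self, cell_id: int) -> Polygon:
        """Flat-topped hexagon for one cell, projected km frame."""
        idx = self.cell_ids.index(cell_id)
        cx, cy = self.centres[idx]
        R = self.circumradius_km
        verts = [
            (cx + R * math.cos(a), cy + R * math.sin(a))
            for a in (k * math.pi / 3.0 for k in range(6))
        ]
        return Polygon(verts)

    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centres)
        return self._tree


def build_hex_grid(
    extent_lonlat,
    cell_area_km2: float,
    projection_centre: Optional[tuple[float, float]] = None,
) -> HexGrid:
    """Tile the projected extent with equal-area flat-topped hexagons.

    Deterministic for a fixed extent and projection centre: cell ids run
    row-major from the lower-left anchor.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    if extent_lonlat.is_empty or extent_lonlat.area == 0.0:
        raise ValueError("degenerate extent")
    proj = (
        LambertEqualArea(*projection_centre)
        if projection_centre is not None
        else projection_for(extent_lonlat)
    )
    extent = proj.project_geometry(extent_lonlat)
    R = hex_circumradius_km(cell_area_km2)
    dx = 1.5 * R                      # column pitch, flat-topped
    dy = math.sqrt(3.0) * R           # row pitch
    minx, miny, maxx, maxy = extent.bounds
    n_cols = int(math.ceil((maxx - minx) / dx)) + 2
    n_rows = int(math.ceil((maxy - miny) / dy)) + 2
    centres = []
    ids = []
    for j in range(n_rows):
        for i in range(n_cols):
            cx = minx + i * dx
            cy = miny + j * dy + (dy / 2.0 if i % 2 else 0.0)
            centres.append((cx, cy))
            ids.append(j * n_cols + i)
    return HexGrid(proj, cell_area_km2, np.array(centres), ids, extent)


def count_points_in_cells(
    grid: HexGrid, records: Sequence[CaptureRecord]
) -> dict[int, int]:
    """Count located records per hexagon.

    Every in-extent point lands in exactly one cell (nearest centre; ties to
    the smaller cell id), so counts sum to the number of in-extent points.
    Out-of-extent points are logged and excluded.
    """
    pts_lonlat = [(r.lon, r.lat) for r in records if r.has_coordinates]
    n_unlocated = len(records) - len(pts_lonlat)
    if n_unlocated:
        logger.info("%d record(s) without coordinates excluded from grid counts", n_unlocated)
    if not pts_lonlat:
        return {}
    lon = np.array([p[0] for p in pts_lonlat])
    lat = np.array([p[1] for p in pts_lonlat])
    x, y = grid.projection.forward(lon, lat)
    pts = np.column_stack([x, y])
    tree = grid.tree()
    # nearest centre = containing hexagon (Voronoi property); near-ties go to
    # the smallest cell id among equidistant centres
    k_query = min(3, len(grid.cell_ids))
    dist, idx = tree.query(pts, k=k_query)
    if k_query == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    counts: dict[int, int] = {}
    n_out = 0
    from shapely.prepared import prep

    extent_prep = prep(grid.extent_proj)
    from shapely.geometry import Point

    for k in range(len(pts)):
        if not extent_prep.intersects(Point(pts[k])):
            n_out += 1
            continue
        d0 = dist[k, 0]
        tied = [int(idx[k, m]) for m in range(idx.shape[1]) if dist[k, m] <= d0 + 1e-9]
        cell = min(grid.cell_ids[i] for i in tied)
        counts[cell] = counts.get(cell, 0) + 1
    if n_out:
        logger.info("%d point(s) outside the grid extent excluded", n_out)
    return counts


TIMEFRAME_ALL = "all"
TIMEFRAME_OLDER = "older"
TIMEFRAME_RECENT = "recent"


def stratify_timeframes(
    records: Sequence[CaptureRecord], thresholds: Thresholds
) -> dict[str, list[CaptureRecord]]:
    """Split records into all / older / recent by the configured split year.

    ``older`` = year <= split, ``recent`` = year >= split + 1; undated records
    appear in ``all`` only.
    """
    split = thresholds.timeframe_split_year
    older = [r for r in records if r.date is not None and r.date.year <= split]
    recent = [r for r in records if r.date is not None and r.date.year > split]
    return {
        TIMEFRAME_ALL: list(records),
        TIMEFRAME_OLDER: older,
        TIMEFRAME_RECENT: recent,
    }


CLS_HOTSPOT = "hotspot"
CLS_AOI = "aoi"
CLS_BACKGROUND = "background"


@dataclass
class CellStat:
    cell_id: int
    timeframe: str
    subset: str
    count: int
    fraction: float
    cls: str


def classify_cells(
    counts: dict[int, int],
    total: int,
    thresholds: Thresholds,
    timeframe: str = TIMEFRAME_ALL,
    subset: str = "all",
) -> list[CellStat]:
    """Hotspot / area-of-interest / background call per non-empty cell.

    fraction > hotspot_frac -> hotspot; aoi_low_frac <= fraction <=
    hotspot_frac -> AOI (both bounds inclusive: exactly 10% is AOI, exactly
    5% is AOI); below -> background.
    """
    if total <= 0:
        if counts:
            logger.warning("zero total events: all cells classified background")
        return [
            CellStat(cid, timeframe, subset, c, 0.0, CLS_BACKGROUND)
            for cid, c in sorted(counts.items())
        ]
    stats = []
    for cid, c in sorted(counts.items()):
        frac = c / total
        if frac > thresholds.hotspot_frac:
            cls = CLS_HOTSPOT
        elif frac >= thresholds.aoi_low_frac:
            cls = CLS_AOI
        else:
            cls = CLS_BACKGROUND
        stats.append(CellStat(cid, timeframe, subset, c, frac, cls))
    return stats


def subset_records(
    records: Sequence[CaptureRecord], subset: str, thresholds: Thresholds
) -> list[CaptureRecord]:
    """Select the event subset for stratified maps (per-event maturity)."""
    if subset == "all":
        return list(records)
    out = []
    for r in records:
        m = classify_maturity(r.sex, r.total_length_cm, thresholds)
        if subset == "mature" and m == Maturity.MATURE:
            out.append(r)
        elif subset == "mature_male" and m == Maturity.MATURE and r.sex is Sex.M:
            out.append(r)
        elif subset == "mature_female" and m == Maturity.MATURE and r.sex is Sex.F:
            out.append(r)
        elif subset == "immature" and m == Maturity.IMMATURE:
            out.append(r)
    return out


def cells_to_geojson(grid: HexGrid, stats: Sequence[CellStat], path) -> None:
    """Write classified cells as lon/lat GeoJSON polygons."""
    features = []
    for st in stats:
        poly = grid.projection.unproject_geometry(grid.cell_polygon(st.cell_id))
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "cell_id": st.cell_id,
                    "timeframe": st.timeframe,
                    "subset": st.subset,
                    "count": st.count,
                    "fraction": st.fraction,
                    "cls": st.cls,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def cells_to_csv(stats: Sequence[CellStat], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "timeframe", "subset", "count", "fraction", "cls"])
        for st in stats:
            w.writerow([st.cell_id, st.timeframe, st.subset, st.count, st.fraction, st.cls])
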