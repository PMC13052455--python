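"""Synthetic coastlines, ports and capture-record datasets with ground truth.

The two real record sources are restricted, so every pipeline stage is
exercised on generated data whose structure mirrors theirs: a handful of
spatially tight capture hotspots holding most of the effort plus a diffuse
background, strong June-October seasonality with a July peak, sex-specific
length distributions around the maturity thresholds, port-proxy coordinate
snapping, a ~10% recapture process with a short-tailed displacement kernel
and lognormal times at liberty, and the record-level corruptions the
curation stage must survive (missing or conflicting sex, shed tags,
specimen claims duplicating tagging records).

Ground truth (individual identity, pre-noise coordinates, true displacement
distances, planted hotspot centres) is captured before any corruption is
applied, so each corruption is independently testable.  All randomness flows
from one ``numpy`` generator seeded from the config, making datasets
reproducible across runs and platforms.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, box, mapping

from .curation import CoastSectors
from .projection import LambertEqualArea
from .records import (
    CaptureRecord,
    EventType,
    LocationProvenance,
    PortTable,
    Programme,
    Sex,
)

SECTOR_NAMES = ["east", "south", "southwest", "west", "northwest", "north"]

# Jun-Oct carries ~80% of capture dates with the July peak at ~20%
DEFAULT_MONTH_WEIGHTS = (
    0.02, 0.02, 0.03, 0.04, 0.05, 0.16, 0.20, 0.16, 0.14, 0.14, 0.02, 0.02
)


@dataclass(frozen=True)
class LengthModel:
    """Truncated-normal total length (cm) for one sex."""

    mean_cm: float
    sd_cm: float
    min_cm: float
    max_cm: float


@dataclass
class SyntheticConfig:
    seed: int = 0
    years: tuple[int, int] = (1972, 2021)
    n_individuals: int = 1000
    coastline: str = "circle_island"  # circle_island | fourier_island | two_islands
    centre_lon: float = -9.0
    centre_lat: float = 53.5
    island_radius_km: float = 25.0
    coast_irregularity: float = 0.15
    n_harmonics: int = 5
    island_separation_km: float = 80.0
    extent_margin_km: float = 45.0
    n_ports: int = 8
    n_sectors: int = 6
    # planted hotspots: (weight, sd_km) per spot; centres are placed in water
    # just offshore at seeded bearings unless given explicitly as lon/lat
    hotspot_weights: tuple[float, ...] = (0.36, 0.19, 0.14)
    hotspot_sd_km: float = 2.5
    hotspot_centres: Optional[tuple[tuple[float, float], ...]] = None
    offshore_km: float = 6.0
    month_weights: tuple[float, ...] = DEFAULT_MONTH_WEIGHTS
    female_ratio: float = 0.6
    length_models: dict[str, LengthModel] = field(
        default_factory=lambda: {
            "M": LengthModel(182.0, 12.0, 150.0, 215.0),
            "F": LengthModel(205.0, 25.0, 150.0, 260.0),
        }
    )
    growth_cm_per_year: float = 2.0
    recapture_prob: float = 0.10
    max_recaptures: int = 4
    dispersal_mean_km: float = 10.0
    long_tail_prob: float = 0.02
    long_tail_max_km: float = 180.0
    liberty_lognorm_mu: float = 5.88
    liberty_lognorm_sigma: float = 0.89
    snap_to_port_prob: float = 0.5
    inch_report_prob: float = 0.05
    missing_sex_prob: float = 0.30
    sex_conflict_prob: float = 0.02
    tag_shed_prob: float = 0.0
    multi_tag_prob: float = 0.10
    isfc_fraction: float = 0.05
    isfc_standalone_frac: float = 0.25
    isfc_min_tl_cm: Optional[float] = None

    def __post_init__(self):
        for name in (
            "recapture_prob", "snap_to_port_prob", "missing_sex_prob",
            "sex_conflict_prob", "tag_shed_prob", "multi_tag_prob",
            "isfc_fraction", "long_tail_prob", "inch_report_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.month_weights) - 1.0) > 1e-9:
            raise ValueError("month_weights must sum to 1")
        if sum(self.hotspot_weights) > 1.0 + 1e-9:
            raise ValueError("hotspot weights must sum to <= 1")
        if self.dispersal_mean_km <= 0:
            raise ValueError("dispersal kernel mean must be positive")


@dataclass
class Geography:
    land: MultiPolygon                    # lon/lat
    extent: Polygon                       # lon/lat
    projection: LambertEqualArea
    ifi_ports: PortTable
    isfc_ports: PortTable
    sectors: CoastSectors
    hotspot_centres: list[tuple[float, float]]   # lon/lat
    hotspot_weights: list[float]
    hotspot_sd_km: float


@dataclass
class SyntheticTruth:
    """Pre-noise ground truth for recovery experiments."""

    individual_of_record: dict[str, str]
    true_sex: dict[str, str]
    true_coords: dict[str, tuple[float, float]]           # record -> lon/lat
    true_distances: dict[str, list[float]]                # individual -> km per interval
    duplicate_pairs: list[tuple[str, str]]                # (ifi_id, isfc_id)
    n_individuals: int
    n_recaptured: int
    hotspot_centres: list[tuple[float, float]]
    hotspot_weights: list[float]

    def true_recapture_rate(self) -> float:
        return self.n_recaptured / self.n_individuals if self.n_individuals else 0.0

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rid, ind in self.individual_of_record.items():
                fh.write(json.dumps({
                    "record_id": rid,
                    "individual": ind,
                    "sex": self.true_sex.get(ind),
                    "lon": self.true_coords[rid][0],
                    "lat": self.true_coords[rid][1],
                }) + "\n")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    geography: Geography
    ifi: list[CaptureRecord]
    isfc: list[CaptureRecord]
    truth: SyntheticTruth


def _island_polygon_proj(rng, cfg: SyntheticConfig, centre_xy=(0.0, 0.0)) -> Polygon:
    """One island outline in the projected km frame."""
    theta = np.linspace(0.0, 2.0 * math.pi, 181)[:-1]
    r = np.full_like(theta, cfg.island_radius_km)
    if cfg.coastline == "fourier_island":
        for k in range(2, cfg.n_harmonics + 2):
            amp = rng.normal(0.0, cfg.coast_irregularity / k) * cfg.island_radius_km
            phase = rng.uniform(0.0, 2.0 * math.pi)
            r = r + amp * np.cos(k * theta + phase)
        r = np.clip(r, 0.25 * cfg.island_radius_km, 2.0 * cfg.island_radius_km)
    xs = centre_xy[0] + r * np.cos(theta)
    ys = centre_xy[1] + r * np.sin(theta)
    poly = Polygon(zip(xs, ys))
    if not poly.is_valid or poly.is_empty:
        raise ValueError("degenerate coastline shape parameters")
    return poly


def generate_coastline(cfg: SyntheticConfig) -> Geography:
    """Seeded island coastline(s) with ports, sectors and hotspot centres.

    Ports sit on the coastline at jittered bearings; sector landmarks are
    evenly spaced coastline points named after compass arcs; hotspot centres
    are placed a few km offshore unless given explicitly.
    """
    rng = np.random.default_rng(cfg.seed)
    proj = LambertEqualArea(cfg.centre_lon, cfg.centre_lat)
    if cfg.coastline in ("circle_island", "fourier_island"):
        polys = [_island_polygon_proj(rng, cfg)]
    elif cfg.coastline == "two_islands":
        half = cfg.island_separation_km / 2.0
        polys = [
            _island_polygon_proj(rng, cfg, (-half, 0.0)),
            _island_polygon_proj(rng, cfg, (half, 0.0)),
        ]
        if polys[0].intersects(polys[1]):
            raise ValueError("islands overlap: increase island_separation_km")
    else:
        raise ValueError(f"unknown coastline kind {cfg.coastline!r}")
    land_proj = MultiPolygon(polys)
    minx, miny, maxx, maxy = land_proj.bounds
    m = cfg.extent_margin_km
    extent_proj = box(minx - m, miny - m, maxx + m, maxy + m)

    main = polys[0]
    ring = main.exterior
    # ports on the coastline of the main island
    port_rows = []
    for k in range(cfg.n_ports):
        d = (k + rng.uniform(0.1, 0.9)) / cfg.n_ports * ring.length
        p = ring.interpolate(d)
        lon, lat = proj.inverse(p.x, p.y)
        port_rows.append((f"Port-{k:02d}", lon, lat))
    ifi_ports = PortTable.from_rows(port_rows)
    # the claim scheme's list was built independently: jitter half the entries
    isfc_rows = []
    for name, lon, lat in port_rows:
        if rng.random() < 0.5:
            x, y = proj.forward(lon, lat)
            x += rng.normal(0.0, 0.2)
            y += rng.normal(0.0, 0.2)
            lon, lat = proj.inverse(x, y)
        isfc_rows.append((name, lon, lat))
    isfc_ports = PortTable.from_rows(isfc_rows)

    n_sec = max(4, min(6, cfg.n_sectors))
    landmarks = []
    for k in range(n_sec):
        p = ring.interpolate(k / n_sec * ring.length)
        landmarks.append((SECTOR_NAMES[k], proj.inverse(p.x, p.y)))
    sectors = CoastSectors(landmarks)

    if cfg.hotspot_centres is not None:
        centres = list(cfg.hotspot_centres)
    else:
        centres = []
        n_spots = len(cfg.hotspot_weights)
        # one bearing per spot, jittered within its own arc so spots stay apart
        fracs = (np.arange(n_spots) + rng.uniform(0.25, 0.75, size=n_spots)) / max(
            1, n_spots
        )
        for f in fracs:
            p = ring.interpolate(f * ring.length)
            # step offshore until clear of land
            step = cfg.offshore_km
            q = np.array([p.x, p.y])
            centre_xy = np.array(main.centroid.coords[0])
            out = q - centre_xy
            out = out / np.linalg.norm(out)
            cand = q + out * step
            while land_proj.contains(Point(cand)):
                cand = cand + out * step
            centres.append(proj.inverse(cand[0], cand[1]))

    land = proj.unproject_geometry(land_proj)
    extent = proj.unproject_geometry(extent_proj)
    return Geography(
        land=land,
        extent=extent,
        projection=proj,
        ifi_ports=ifi_ports,
        isfc_ports=isfc_ports,
        sectors=sectors,
        hotspot_centres=centres,
        hotspot_weights=list(cfg.hotspot_weights),
        hotspot_sd_km=cfg.hotspot_sd_km,
    )


def _sample_date(rng, cfg: SyntheticConfig) -> dt.date:
    year = int(rng.integers(cfg.years[0], cfg.years[1] + 1))
    month = int(rng.choice(np.arange(1, 13), p=np.asarray(cfg.month_weights)))
    if month == 12:
        n_days = 31
    else:
        n_days = (dt.date(year, month + 1, 1) - dt.date(year, month, 1)).days
    day = int(rng.integers(1, n_days + 1))
    return dt.date(year, month, day)


def _sample_length(rng, model: LengthModel) -> float:
    for _ in range(1000):
        v = rng.normal(model.mean_cm, model.sd_cm)
        if model.min_cm <= v <= model.max_cm:
            return float(v)
    return model.mean_cm


class _WaterSampler:
    """Rejection sampler for points in water inside the extent."""

    def __init__(self, geo: Geography):
        from shapely.prepared import prep

        self.proj = geo.projection
        self.land_proj = self.proj.project_geometry(geo.land)
        self.extent_proj = self.proj.project_geometry(geo.extent)
        self._land_prep = prep(self.land_proj)
        self._extent_prep = prep(self.extent_proj)
        self.bounds = self.extent_proj.bounds

    def in_water(self, xy) -> bool:
        p = Point(xy)
        return self._extent_prep.contains(p) and not self._land_prep.intersects(p)

    def gaussian(self, rng, centre_xy, sd_km) -> np.ndarray:
        for _ in range(1000):
            cand = np.asarray(centre_xy) + rng.normal(0.0, sd_km, size=2)
            if self.in_water(cand):
                return cand
        raise RuntimeError("water rejection sampling failed near hotspot centre")

    def uniform(self, rng) -> np.ndarray:
        minx, miny, maxx, maxy = self.bounds
        for _ in range(10000):
            cand = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
            if self.in_water(cand):
                return cand
        raise RuntimeError("water rejection sampling failed in extent")

    def displaced(self, rng, from_xy, distance_km) -> tuple[np.ndarray, float]:
        """Point at the given kernel distance from ``from_xy``, in water.

        The bearing is resampled until the endpoint is wet; the distance is
        kept so the planted kernel is preserved.  If no bearing works the
        distance is redrawn smaller.
        """
        d = distance_km
        for _ in range(30):
            for _ in range(200):
                b = rng.uniform(0.0, 2.0 * math.pi)
                cand = np.asarray(from_xy) + d * np.array([math.cos(b), math.sin(b)])
                if self.in_water(cand):
                    return cand, d
            d *= 0.7
        raise RuntimeError("no water endpoint found for displacement")


def generate_dataset(
    cfg: SyntheticConfig, geography: Optional[Geography] = None
) -> SyntheticDataset:
    """Generate the two programmes' record sets plus ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    geo = geography or generate_coastline(cfg)
    sampler = _WaterSampler(geo)
    proj = geo.projection
    centres_xy = [np.array(proj.forward(*c)) for c in geo.hotspot_centres]
    weights = np.array(geo.hotspot_weights, dtype=float)
    diffuse = max(0.0, 1.0 - weights.sum())
    mix = np.append(weights, diffuse)
    mix = mix / mix.sum()

    ifi: list[CaptureRecord] = []
    truth_ind: dict[str, str] = {}
    truth_sex: dict[str, str] = {}
    truth_coords: dict[str, tuple[float, float]] = {}
    truth_dist: dict[str, list[float]] = {}
    n_recaptured = 0
    next_tag = 0

    def new_tag() -> str:
        nonlocal next_tag
        t = f"TAG-{next_tag:05d}"
        next_tag += 1
        return t

    span_end = dt.date(cfg.years[1], 12, 31)
    row = 0

    for ind_idx in range(cfg.n_individuals):
        ind_id = f"SKATE-{ind_idx:05d}"
        sex = Sex.F if rng.random() < cfg.female_ratio else Sex.M
        truth_sex[ind_id] = sex.value
        tl0 = _sample_length(rng, cfg.length_models[sex.value])
        comp = int(rng.choice(len(mix), p=mix))
        if comp < len(centres_xy):
            xy = sampler.gaussian(rng, centres_xy[comp], geo.hotspot_sd_km)
        else:
            xy = sampler.uniform(rng)
        date0 = _sample_date(rng, cfg)
        tags = [new_tag()]
        if rng.random() < cfg.multi_tag_prob:
            tags.append(new_tag())

        n_rec = 0
        while n_rec < cfg.max_recaptures and rng.random() < cfg.recapture_prob:
            n_rec += 1
        if n_rec > 0:
            n_recaptured += 1
        truth_dist[ind_id] = []

        xy_k, date_k, tl_k = xy, date0, tl0
        tags_k = list(tags)
        for k in range(n_rec + 1):
            rid = f"IFI-{row:06d}"
            row += 1
            lon, lat = proj.inverse(xy_k[0], xy_k[1])
            truth_ind[rid] = ind_id
            truth_coords[rid] = (lon, lat)
            # record-level noise
            rep_lon, rep_lat, prov, port = lon, lat, LocationProvenance.EXACT, None
            if rng.random() < cfg.snap_to_port_prob:
                port, (rep_lon, rep_lat) = _nearest_port(geo.ifi_ports, lon, lat)
                prov = LocationProvenance.PORT_PROXY
            rep_sex = sex
            if rng.random() < cfg.missing_sex_prob:
                rep_sex = Sex.U
            elif k > 0 and rng.random() < cfg.sex_conflict_prob:
                rep_sex = Sex.M if sex is Sex.F else Sex.F
            ifi.append(
                CaptureRecord(
                    record_id=rid,
                    programme=Programme.IFI,
                    tagger_id=f"T-{int(rng.integers(0, max(2, cfg.n_individuals // 12))):04d}",
                    tag_ids=tuple(tags_k),
                    event_type=EventType.CAPTURE if k == 0 else EventType.RECAPTURE,
                    date=date_k,
                    sex=rep_sex,
                    total_length_cm=round(tl_k, 1),
                    lon=rep_lon,
                    lat=rep_lat,
                    location_provenance=prov,
                    port_name=port,
                )
            )
            if k == n_rec:
                break
            # next event: displacement kernel + lognormal liberty days
            if rng.random() < cfg.long_tail_prob:
                d = float(rng.uniform(0.0, cfg.long_tail_max_km))
            else:
                d = float(rng.exponential(cfg.dispersal_mean_km))
            xy_k, d = sampler.displaced(rng, xy_k, d)
            truth_dist[ind_id].append(d)
            days = int(rng.lognormal(cfg.liberty_lognorm_mu, cfg.liberty_lognorm_sigma))
            date_k = min(date_k + dt.timedelta(days=days), span_end)
            tl_k = min(tl_k + cfg.growth_cm_per_year * days / 365.25, 260.0)
            if rng.random() < cfg.tag_shed_prob:
                tags_k = [new_tag()]  # shed: recapture looks like a new animal

    # specimen claims: duplicates of tagging events plus standalone claims
    isfc: list[CaptureRecord] = []
    duplicate_pairs: list[tuple[str, str]] = []
    claim_row = 0
    for rec in ifi:
        if rng.random() < cfg.isfc_fraction:
            cid = f"ISFC-{claim_row:06d}"
            claim_row += 1
            isfc.append(
                replace(
                    rec,
                    record_id=cid,
                    programme=Programme.ISFC,
                    tagger_id=f"C-{rec.tagger_id}",
                    tag_ids=(),
                    event_type=EventType.CAPTURE,
                )
            )
            duplicate_pairs.append((rec.record_id, cid))
            truth_ind[cid] = truth_ind[rec.record_id]
            truth_coords[cid] = truth_coords[rec.record_id]
    n_standalone = int(round(cfg.isfc_standalone_frac * cfg.n_individuals))
    for j in range(n_standalone):
        cid = f"ISFC-{claim_row:06d}"
        claim_row += 1
        ind_id = f"CLAIM-{j:05d}"
        sex = Sex.F if rng.random() < cfg.female_ratio else Sex.M
        tl = _sample_length(rng, cfg.length_models[sex.value])
        if cfg.isfc_min_tl_cm is not None and tl < cfg.isfc_min_tl_cm:
            continue
        comp = int(rng.choice(len(mix), p=mix))
        xy = (
            sampler.gaussian(rng, centres_xy[comp], geo.hotspot_sd_km)
            if comp < len(centres_xy)
            else sampler.uniform(rng)
        )
        lon, lat = proj.inverse(xy[0], xy[1])
        truth_sex[ind_id] = sex.value
        truth_ind[cid] = ind_id
        truth_coords[cid] = (lon, lat)
        rep_lon, rep_lat, prov, port = lon, lat, LocationProvenance.EXACT, None
        if rng.random() < cfg.snap_to_port_prob:
            port, (rep_lon, rep_lat) = _nearest_port(geo.isfc_ports, lon, lat)
            prov = LocationProvenance.PORT_PROXY
        isfc.append(
            CaptureRecord(
                record_id=cid,
                programme=Programme.ISFC,
                tagger_id=f"C-{int(rng.integers(0, max(2, n_standalone // 4))):04d}",
                date=_sample_date(rng, cfg),
                sex=Sex.U if rng.random() < cfg.missing_sex_prob else sex,
                total_length_cm=round(tl, 1),
                lon=rep_lon,
                lat=rep_lat,
                location_provenance=prov,
                port_name=port,
            )
        )

    truth = SyntheticTruth(
        individual_of_record=truth_ind,
        true_sex=truth_sex,
        true_coords=truth_coords,
        true_distances=truth_dist,
        duplicate_pairs=duplicate_pairs,
        n_individuals=cfg.n_individuals,
        n_recaptured=n_recaptured,
        hotspot_centres=list(geo.hotspot_centres),
        hotspot_weights=list(geo.hotspot_weights),
    )
    return SyntheticDataset(cfg, geo, ifi, isfc, truth)


def _nearest_port(ports: PortTable, lon: float, lat: float):
    from .dispersal import geodesic_km

    name = min(
        ports.entries,
        key=lambda n: (geodesic_km((lon, lat), ports.entries[n]), n),
    )
    return name, ports.entries[name]


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass
class RecoveryMetrics:
    hotspot_precision: float
    hotspot_recall: float
    dispersal_mae_km: Optional[float]
    estimated_recapture_rate: Optional[float]
    true_recapture_rate: float


def planted_hotspot_cells(truth: SyntheticTruth, grid) -> set[int]:
    """Grid cells containing the planted hotspot centres."""
    from .records import CaptureRecord as _CR

    cells = set()
    for lon, lat in truth.hotspot_centres:
        probe = _CR(record_id="probe", programme=Programme.IFI, tagger_id="",
                    lon=lon, lat=lat)
        from .hexgrid import count_points_in_cells

        counts = count_points_in_cells(grid, [probe])
        cells.update(counts.keys())
    return cells


def evaluate_recovery(
    truth: SyntheticTruth,
    cells,
    dispersal,
    grid=None,
    histories=None,
) -> RecoveryMetrics:
    """Compare pipeline output against planted ground truth.

    Hotspot precision/recall compare cells classified ``hotspot`` with the
    cells containing planted centres; dispersal MAE matches measured interval
    distances to the planted kernel draws per individual; the recapture-rate
    pair quantifies bias (for example under tag shedding).
    """
    precision = recall = float("nan")
    if grid is not None and cells is not None:
        planted = planted_hotspot_cells(truth, grid)
        predicted = {c.cell_id for c in cells if c.cls == "hotspot"}
        tp = len(planted & predicted)
        precision = tp / len(predicted) if predicted else (1.0 if not planted else 0.0)
        recall = tp / len(planted) if planted else 1.0

    mae = None
    if dispersal:
        errors = []
        by_ind: dict[str, list] = {}
        for res in dispersal:
            by_ind.setdefault(res.individual_id, []).append(res)
        for ind_id, results in by_ind.items():
            true = truth.true_distances.get(_true_individual(ind_id, truth, histories))
            if true is None or len(true) != len(results):
                continue
            for res in sorted(results, key=lambda r: r.interval_index):
                errors.append(abs(res.distance_km - true[res.interval_index]))
        mae = float(np.mean(errors)) if errors else None

    est_rate = None
    if histories is not None and histories:
        est_rate = sum(1 for h in histories if h.n_recaptures > 0) / len(histories)
    return RecoveryMetrics(
        hotspot_precision=precision,
        hotspot_recall=recall,
        dispersal_mae_km=mae,
        estimated_recapture_rate=est_rate,
        true_recapture_rate=truth.true_recapture_rate(),
    )


def _true_individual(history_id: str, truth: SyntheticTruth, histories) -> Optional[str]:
    if histories is not None:
        for h in histories:
            if h.individual_id == history_id and h.events:
                return truth.individual_of_record.get(h.events[0].record_id)
    # history ids are "ind-<first record id>"
    rid = history_id.removeprefix("ind-")
    return truth.individual_of_record.get(rid)


# ---------------------------------------------------------------------------
# serialisation


def write_geojson(geom, path, properties: Optional[dict] = None) -> None:
    feat = {"type": "Feature", "geometry": mapping(geom), "properties": properties or {}}
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feat]}, fh)


def write_ports_geojson(ports: PortTable, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"port_name": name},
        }
        for name, (lon, lat) in ports.entries.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset in the on-disk formats the pipeline consumes.

    IFI and ISFC dialect CSVs (a seeded share of IFI lengths is written in
    inches with the unit flag, exercising digitisation), port tables,
    coastline/extent GeoJSON, sector landmarks and truth JSONL.
    """
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(ds.config.seed + 2)
    with open(outdir / "ifi_records.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["tagger_id", "tag_id_1", "tag_id_2", "tag_id_3", "tag_type", "event_type",
             "date", "sex", "length_value", "length_unit", "wingspan_cm", "weight_kg",
             "lon", "lat", "port_name", "comments"]
        )
        for r in ds.ifi:
            tags = list(r.tag_ids) + ["", "", ""]
            if r.total_length_cm is not None and rng.random() < ds.config.inch_report_prob:
                length_value, unit = repr(r.total_length_cm / 2.54), "in"
            elif r.total_length_cm is not None:
                length_value, unit = repr(r.total_length_cm), "cm"
            else:
                length_value, unit = "", ""
            w.writerow([
                r.tagger_id, tags[0], tags[1], tags[2], "dart", r.event_type.value,
                r.date.strftime("%d/%m/%Y") if r.date else "", r.sex.value if r.sex is not Sex.U else "",
                length_value, unit, "", "",
                "" if r.port_name else repr(r.lon), "" if r.port_name else repr(r.lat),
                r.port_name or "", r.comments,
            ])
    with open(outdir / "isfc_records.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["claimant_id", "skipper_id", "date", "sex", "total_length_cm",
             "wingspan_cm", "weight_kg", "port_name", "lon", "lat", "platform",
             "comments"]
        )
        for r in ds.isfc:
            w.writerow([
                r.tagger_id, "", r.date.strftime("%d/%m/%Y") if r.date else "",
                r.sex.value if r.sex is not Sex.U else "",
                repr(r.total_length_cm) if r.total_length_cm is not None else "",
                "", "", r.port_name or "",
                repr(r.lon) if r.lon is not None else "",
                repr(r.lat) if r.lat is not None else "",
                "boat", r.comments,
            ])
    ds.geography.ifi_ports.write_csv(outdir / "ifi_ports.csv")
    ds.geography.isfc_ports.write_csv(outdir / "isfc_ports.csv")
    write_geojson(ds.geography.land, outdir / "coastline.geojson")
    write_geojson(ds.geography.extent, outdir / "extent.geojson")
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(lonlat)},
            "properties": {"sector": name, "order": k},
        }
        for k, (name, lonlat) in enumerate(ds.geography.sectors.landmarks)
    ]
    with open(outdir / "sectors.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    ds.truth.write_jsonl(outdir / "truth.jsonl")
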