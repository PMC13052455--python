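"""Equal-area map projection used by every planar operation in the pipeline.

All gridding, tessellation and land-intersection work happens in a single
Lambert azimuthal equal-area (LAEA) frame on a sphere of authalic radius
6371.0088 km, centred on the study extent.  Equal-area is required for cell
and triangle areas quoted in km^2 to be meaningful; azimuthal keeps local
distance distortion small over a study area a few hundred km across.

Forward/inverse formulas are the standard spherical LAEA closed forms.
Coordinates are (lon, lat) in decimal degrees WGS84 on the geographic side
and (x, y) in kilometres on the projected side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import transform as shp_transform

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class LambertEqualArea:
    """Spherical Lambert azimuthal equal-area projection, km units."""

    centre_lon: float
    centre_lat: float
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km. Accepts scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam = np.radians(lon - self.centre_lon)
        phi = np.radians(lat)
        phi0 = np.radians(self.centre_lat)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # antipode of the centre maps to infinity; never reached for study areas
        k = np.sqrt(2.0 / denom)
        x = self.radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.radius_km * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees. Accepts scalars or arrays."""
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        rho = np.hypot(x, y)
        phi0 = np.radians(self.centre_lat)
        with np.errstate(invalid="ignore"):
            c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
            sin_c, cos_c = np.sin(c), np.cos(c)
            safe_rho = np.where(rho == 0.0, 1.0, rho)
            phi = np.arcsin(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho)
            lam = np.arctan2(
                x * sin_c, safe_rho * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c
            )
        phi = np.where(rho == 0.0, phi0, phi)
        lam = np.where(rho == 0.0, 0.0, lam)
        lon = self.centre_lon + np.degrees(lam)
        lat = np.degrees(phi)
        if np.ndim(lon) == 0:
            return float(lon), float(lat)
        return lon, lat

    def project_geometry(self, geom):
        """Project a shapely geometry from lon/lat to the planar km frame."""
        return shp_transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom):
        """Inverse-project a shapely geometry from km back to lon/lat."""
        return shp_transform(lambda x, y: self.inverse(x, y), geom)


def geometry_centroid_lonlat(geom) -> tuple[float, float]:
    """Rough lon/lat centroid used to pick a projection centre."""
    c = geom.centroid
    return float(c.x), float(c.y)


def projection_for(geom) -> LambertEqualArea:
    """LAEA projection centred on a lon/lat geometry's centroid."""
    lon, lat = geometry_centroid_lonlat(geom)
    return LambertEqualArea(lon, lat)


def as_multipolygon(geom) -> MultiPolygon:
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    raise TypeError(f"expected (Multi)Polygon, got {geom.geom_type}")
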