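"""Geographic primitives: great-circle distances, spherical cell areas, and
uniform lon/lat grid indexing.

All coordinates are decimal degrees (WGS84 lon/lat order assumed). Distances
use the haversine formula on a sphere of radius 6371 km; at the sampling radii
this package works with (≤ tens of km) the difference from an ellipsoidal
geodesic is far below a grid-cell diameter.

Two kinds of spatial unit coexist:

* survey **tiles** — the atlas' native recording unit, 10'×6' ordnance-map
  sheets ("Messtischblatt", MTB) or their 5'×3' quarter subdivisions, addressed
  by their center point;
* **computational cells** — a uniform fine raster (default 30"×18", i.e. one
  hundredth of a quarter tile, ≈0.33 km² in central Germany) onto which point
  records are binned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

ARCSEC_PER_DEG = 3600.0
ARCMIN_PER_DEG = 60.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "GridSpec",
    "CellIndex",
    "Tile",
    "great_circle_distance",
    "haversine_km",
    "cell_area",
    "locate_cell",
    "neighborhood",
]


class OutOfRegionError(ValueError):
    """A point falls outside the configured study bounding box."""


def _validate_lonlat(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon!r} outside [-180, 180]")
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat!r} outside [-90, 90]")


@dataclass(frozen=True, order=True)
class GeoPoint:
    """A WGS84 location: longitude and latitude in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        _validate_lonlat(self.lon, self.lat)


@dataclass(frozen=True)
class CellIndex:
    """0-based (column, row) address of a computational grid cell."""

    col: int
    row: int


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between lon/lat pairs (vectorised).

    Accepts scalars or numpy arrays (degrees); broadcasts like numpy.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance between two points, in km."""
    return float(haversine_km(a.lon, a.lat, b.lon, b.lat))


def cell_area(lon_extent_arcmin: float, lat_extent_arcmin: float, lat: float) -> float:
    """Area in km² of a spherical lon/lat quadrangle centered at latitude `lat`.

    Extents are in arc-minutes. Exact on the sphere:
    ``A = R² Δλ (sin φ_n − sin φ_s)`` with the quadrangle centered at ``lat``.
    A 10'×6' survey tile spans ≈118 km² at 55°N down the monotone cosine taper
    to ≈140 km² at 47.3°N; a 30"×18" computational cell is ≈0.33 km².
    """
    if lon_extent_arcmin <= 0 or lat_extent_arcmin <= 0:
        raise ValueError("extents must be positive")
    if not abs(lat) < 90.0:
        raise ValueError("|lat| must be < 90")
    dlam = math.radians(lon_extent_arcmin / ARCMIN_PER_DEG)
    half_dphi = lat_extent_arcmin / ARCMIN_PER_DEG / 2.0
    north = math.radians(lat + half_dphi)
    south = math.radians(lat - half_dphi)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(north) - math.sin(south))


@dataclass(frozen=True)
class GridSpec:
    """Uniform computational grid anchored at its south-west corner.

    Cells are half-open ``[west, east) × [south, north)``: a point on a shared
    edge belongs to the cell on its east/north side.
    """

    origin: GeoPoint
    lon_step_arcsec: float
    lat_step_arcsec: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.lon_step_arcsec <= 0 or self.lat_step_arcsec <= 0:
            raise ValueError("grid steps must be positive")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")

    @classmethod
    def from_bbox(
        cls,
        lon_min: float,
        lat_min: float,
        lon_max: float,
        lat_max: float,
        lon_step_arcsec: float = 30.0,
        lat_step_arcsec: float = 18.0,
    ) -> "GridSpec":
        """Grid covering a bounding box (cells may overhang the NE edge)."""
        n_cols = math.ceil((lon_max - lon_min) * ARCSEC_PER_DEG / lon_step_arcsec)
        n_rows = math.ceil((lat_max - lat_min) * ARCSEC_PER_DEG / lat_step_arcsec)
        return cls(GeoPoint(lon_min, lat_min), lon_step_arcsec, lat_step_arcsec, n_cols, n_rows)

    @classmethod
    def germany_default(cls, lon_step_arcsec: float = 30.0, lat_step_arcsec: float = 18.0) -> "GridSpec":
        """Default study region 5–16°E, 47–56°N at the 30"×18" resolution."""
        return cls.from_bbox(5.0, 47.0, 16.0, 56.0, lon_step_arcsec, lat_step_arcsec)

    @property
    def lon_step_deg(self) -> float:
        return self.lon_step_arcsec / ARCSEC_PER_DEG

    @property
    def lat_step_deg(self) -> float:
        return self.lat_step_arcsec / ARCSEC_PER_DEG

    @property
    def lon_max(self) -> float:
        return self.origin.lon + self.n_cols * self.lon_step_deg

    @property
    def lat_max(self) -> float:
        return self.origin.lat + self.n_rows * self.lat_step_deg

    def contains(self, p: GeoPoint) -> bool:
        return (self.origin.lon <= p.lon < self.lon_max) and (self.origin.lat <= p.lat < self.lat_max)

    def locate(self, p: GeoPoint) -> CellIndex:
        if not self.contains(p):
            raise OutOfRegionError(f"point ({p.lon}, {p.lat}) outside grid bounding box")
        col = int(math.floor((p.lon - self.origin.lon) / self.lon_step_deg))
        row = int(math.floor((p.lat - self.origin.lat) / self.lat_step_deg))
        # guard float edge cases at the NE boundary of the last cell
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return CellIndex(col, row)

    def cell_center(self, cell: CellIndex) -> GeoPoint:
        return GeoPoint(
            self.origin.lon + (cell.col + 0.5) * self.lon_step_deg,
            self.origin.lat + (cell.row + 0.5) * self.lat_step_deg,
        )

    def cell_center_arrays(self, cols: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised cell centers: (lons, lats) for parallel col/row arrays."""
        lons = self.origin.lon + (np.asarray(cols, dtype=float) + 0.5) * self.lon_step_deg
        lats = self.origin.lat + (np.asarray(rows, dtype=float) + 0.5) * self.lat_step_deg
        return lons, lats

    def cells_within_km(self, p: GeoPoint, r_km: float) -> tuple[np.ndarray, np.ndarray]:
        """(cols, rows) of every cell whose center lies within r_km of p.

        Scans only the bounding index window implied by r_km, then applies the
        exact haversine filter (closed ball, ties at exactly r included).
        """
        # degrees per km, padded by one cell to be safe against the window cut
        dlat = r_km / 111.0 + self.lat_step_deg
        coslat = max(math.cos(math.radians(p.lat)), 1e-9)
        dlon = r_km / (111.0 * coslat) + self.lon_step_deg
        c0 = max(0, int((p.lon - dlon - self.origin.lon) / self.lon_step_deg))
        c1 = min(self.n_cols - 1, int((p.lon + dlon - self.origin.lon) / self.lon_step_deg))
        r0 = max(0, int((p.lat - dlat - self.origin.lat) / self.lat_step_deg))
        r1 = min(self.n_rows - 1, int((p.lat + dlat - self.origin.lat) / self.lat_step_deg))
        if c1 < c0 or r1 < r0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        cols, rows = cols.ravel(), rows.ravel()
        lons, lats = self.cell_center_arrays(cols, rows)
        keep = haversine_km(p.lon, p.lat, lons, lats) <= r_km
        return cols[keep], rows[keep]


def locate_cell(p: GeoPoint, grid: GridSpec) -> CellIndex:
    """Cell containing p under the half-open convention; raises OutOfRegionError."""
    return grid.locate(p)


def neighborhood(p: GeoPoint, r_km: float, center_lons, center_lats) -> np.ndarray:
    """Boolean mask over candidate centers: True where dist(p, c) ≤ r_km.

    A closed ball — a center at exactly r_km is included. The r = 0 exact-unit
    retrieval convention (containing tile/cell regardless of distance to its
    center) is a property of support lookup, not of this geometric predicate.
    """
    if r_km < 0:
        raise ValueError("radius must be non-negative")
    return haversine_km(p.lon, p.lat, np.asarray(center_lons), np.asarray(center_lats)) <= r_km


@dataclass(frozen=True)
class Tile:
    """A survey tile addressed by its center, with extents in arc-minutes.

    resolution_level is 'full' (10'×6') or 'quarter' (5'×3'); quarter extents
    are half of the full extents in each dimension.
    """

    id: str
    center: GeoPoint
    lon_extent_arcmin: float
    lat_extent_arcmin: float
    resolution_level: str = "quarter"

    def __post_init__(self) -> None:
        if self.lon_extent_arcmin <= 0 or self.lat_extent_arcmin <= 0:
            raise ValueError("tile extents must be positive")
        if self.resolution_level not in ("full", "quarter"):
            raise ValueError(f"unknown resolution level {self.resolution_level!r}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) in degrees."""
        half_lon = self.lon_extent_arcmin / ARCMIN_PER_DEG / 2.0
        half_lat = self.lat_extent_arcmin / ARCMIN_PER_DEG / 2.0
        return (
            self.center.lon - half_lon,
            self.center.lat - half_lat,
            self.center.lon + half_lon,
            self.center.lat + half_lat,
        )

    def contains(self, p: GeoPoint) -> bool:
        lon_min, lat_min, lon_max, lat_max = self.bounds
        return lon_min <= p.lon < lon_max and lat_min <= p.lat < lat_max

    def area_km2(self) -> float:
        return cell_area(self.lon_extent_arcmin, self.lat_extent_arcmin, self.center.lat)
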