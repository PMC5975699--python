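"""Shared fixtures: small random problem instances built twice over — once as
package objects, once as the plain tuples the naive oracle consumes."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pytest

from florarec import (
    GeoPoint,
    GridSpec,
    PointOccurrence,
    PresenceAbsenceDataset,
    Recommender,
    TestRecord,
    Tile,
)
from _oracle import OracleGrid

# not a test class, despite the name
TestRecord.__test__ = False


@dataclass
class Instance:
    grid: GridSpec
    oracle_grid: OracleGrid
    records: list[PointOccurrence]
    oracle_records: list[tuple]
    presence: PresenceAbsenceDataset
    oracle_tiles: list[tuple]
    taxa: list[str]


def make_instance(seed: int, max_taxa: int = 20, max_records: int = 50) -> Instance:
    rng = np.random.default_rng(seed)
    n_cols = int(rng.integers(8, 15))
    n_rows = int(rng.integers(8, 15))
    origin = GeoPoint(10.0, 50.0)
    grid = GridSpec(origin, 30.0, 18.0, n_cols, n_rows)
    ogrid = OracleGrid(origin.lon, origin.lat, grid.lon_step_deg, grid.lat_step_deg, n_cols, n_rows)

    taxa = [f"t{i:02d}" for i in range(int(rng.integers(5, max_taxa + 1)))]

    def random_point(pad_cells=0.5):
        lon = float(rng.uniform(origin.lon + pad_cells * grid.lon_step_deg, grid.lon_max - pad_cells * grid.lon_step_deg))
        lat = float(rng.uniform(origin.lat + pad_cells * grid.lat_step_deg, grid.lat_max - pad_cells * grid.lat_step_deg))
        return GeoPoint(lon, lat)

    records, oracle_records = [], []
    for _ in range(int(rng.integers(10, max_records + 1))):
        taxon = taxa[int(rng.integers(len(taxa)))]
        loc = random_point()
        unc = float(rng.uniform(100, 1500))
        u = rng.random()
        if u < 0.7:
            date = _dt.date(2015, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
            plausible = True
        elif u < 0.85:
            date, plausible = None, False
        else:
            date, plausible = _dt.date(1970, 1, 1), False
        records.append(PointOccurrence(taxon, loc, date, unc, plausible))
        oracle_records.append((taxon, loc.lon, loc.lat, unc, date, plausible))

    # survey tiles: a small aligned lattice of 2'x1.2' quarter tiles
    tile_lon, tile_lat = 2.0 / 60.0, 1.2 / 60.0
    tiles, presence, oracle_tiles = {}, set(), []
    n_tiles = int(rng.integers(2, 7))
    for k in range(n_tiles):
        tc = int(rng.integers(0, max(1, int((grid.lon_max - origin.lon) / tile_lon))))
        tr = int(rng.integers(0, max(1, int((grid.lat_max - origin.lat) / tile_lat))))
        tid = f"q{tc}_{tr}"
        tile = Tile(
            id=tid,
            center=GeoPoint(origin.lon + (tc + 0.5) * tile_lon, origin.lat + (tr + 0.5) * tile_lat),
            lon_extent_arcmin=2.0,
            lat_extent_arcmin=1.2,
            resolution_level="quarter",
        )
        tiles[tid] = tile
        for taxon in taxa:
            if rng.random() < 0.4:
                if (tid, taxon) not in presence:
                    presence.add((tid, taxon))
                    oracle_tiles.append((taxon, tile.center.lon, tile.center.lat, tile.bounds))
    pa = PresenceAbsenceDataset(tiles=tiles, presence=presence)

    return Instance(grid, ogrid, records, oracle_records, pa, oracle_tiles, taxa)


def make_query(seed: int, inst: Instance) -> tuple[GeoPoint, _dt.date, float]:
    rng = np.random.default_rng(seed + 10_000)
    g = inst.grid
    lon = float(rng.uniform(g.origin.lon + 0.3 * g.lon_step_deg, g.lon_max - 0.3 * g.lon_step_deg))
    lat = float(rng.uniform(g.origin.lat + 0.3 * g.lat_step_deg, g.lat_max - 0.3 * g.lat_step_deg))
    date = _dt.date(2017, int(rng.integers(1, 13)), 15)
    r_km = float(rng.uniform(0.5, 5.0))
    return GeoPoint(lon, lat), date, r_km


@pytest.fixture
def instance_factory():
    return make_instance


@pytest.fixture
def query_factory():
    return make_query
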