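"""Binning point occurrences onto the computational grid.

Every record is treated as a circle centered on its coordinates with radius
equal to its stated coordinate uncertainty; the encounter expectation is
highest at the center and decays linearly to zero at the circle's edge. The
kernel is sampled at cell centers and renormalised so each record contributes
exactly unit mass — counts stay interpretable as "number of observations".

Dated records additionally spread their unit mass over one or two calendar
months in proportion to the observation day's distance from mid-month,
yielding the per-cell, per-month phenology table the temporal scoring
strategy consumes.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_grid import CellIndex, GeoPoint, GridSpec, haversine_km
from .ingest import PointOccurrence

__all__ = ["OccurrenceRaster", "spatial_weights", "month_weights", "build_raster"]


def spatial_weights(rec: PointOccurrence, grid: GridSpec) -> dict[CellIndex, float]:
    """Distribute one record's unit mass over cells by the linear-decay kernel.

    weight(c) ∝ max(0, 1 − d(center(c), location)/u) with u the record's
    uncertainty radius; weights are renormalised to sum to 1. If the circle
    covers no cell center at positive kernel value, the whole mass goes to the
    containing cell.
    """
    u_km = rec.uncertainty_m / 1000.0
    cols, rows = grid.cells_within_km(rec.location, u_km)
    if cols.size:
        lons, lats = grid.cell_center_arrays(cols, rows)
        d = haversine_km(rec.location.lon, rec.location.lat, lons, lats)
        kern = np.maximum(0.0, 1.0 - d / u_km)
        total = kern.sum()
        if total > 0:
            kern /= total
            return {
                CellIndex(int(c), int(r)): float(w)
                for c, r, w in zip(cols, rows, kern)
                if w > 0
            }
    return {grid.locate(rec.location): 1.0}


def _mid_month_day(year: int, month: int) -> int:
    dim = calendar.monthrange(year, month)[1]
    return math.ceil((dim + 1) / 2)


def month_weights(d: _dt.date) -> dict[int, float]:
    """Split an observation date over at most two adjacent monthly bins.

    The observation's own month receives 1 − |day − mid|/days_in_month; the
    remainder goes to the calendar-adjacent month on the side of the offset,
    wrapping December–January. A mid-month observation maps to a single bin.
    """
    dim = calendar.monthrange(d.year, d.month)[1]
    mid = _mid_month_day(d.year, d.month)
    offset = d.day - mid
    own = 1.0 - abs(offset) / dim
    if offset == 0:
        return {d.month: 1.0}
    other = d.month + (1 if offset > 0 else -1)
    other = (other - 1) % 12 + 1
    return {d.month: own, other: 1.0 - own}


@dataclass
class OccurrenceRaster:
    """Sparse per-cell weighted counts plus per-month phenology mass.

    counts: DataFrame(col, row, taxon_id, weight) — one row per occupied
    (cell, taxon); month_counts: DataFrame(col, row, taxon_id, month, weight)
    over date-plausible records only. For each dated record its month mass
    equals its count mass (both are unit per record).
    """

    grid: GridSpec
    counts: pd.DataFrame
    month_counts: pd.DataFrame
    n_records: int = 0
    n_dated_records: int = 0

    _taxon_cells: dict | None = field(default=None, repr=False, compare=False)

    COUNT_COLS = ["col", "row", "taxon_id", "weight"]
    MONTH_COLS = ["col", "row", "taxon_id", "month", "weight"]

    @property
    def taxa(self) -> set[str]:
        return set(self.counts["taxon_id"].unique())

    def add(self, other: "OccurrenceRaster") -> "OccurrenceRaster":
        if other.grid != self.grid:
            raise ValueError("rasters live on different grids")
        counts = (
            pd.concat([self.counts, other.counts])
            .groupby(["col", "row", "taxon_id"], as_index=False)["weight"]
            .sum()
        )
        months = (
            pd.concat([self.month_counts, other.month_counts])
            .groupby(["col", "row", "taxon_id", "month"], as_index=False)["weight"]
            .sum()
        )
        return OccurrenceRaster(
            self.grid, counts, months, self.n_records + other.n_records, self.n_dated_records + other.n_dated_records
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.csv", index=False)
        self.month_counts.to_csv(out / "month_counts.csv", index=False)
        g = self.grid
        meta = {
            "origin_lon": g.origin.lon,
            "origin_lat": g.origin.lat,
            "lon_step_arcsec": g.lon_step_arcsec,
            "lat_step_arcsec": g.lat_step_arcsec,
            "n_cols": g.n_cols,
            "n_rows": g.n_rows,
            "n_records": self.n_records,
            "n_dated_records": self.n_dated_records,
        }
        (out / "grid.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "OccurrenceRaster":
        p = Path(in_dir)
        meta = json.loads((p / "grid.json").read_text())
        grid = GridSpec(
            GeoPoint(meta["origin_lon"], meta["origin_lat"]),
            meta["lon_step_arcsec"],
            meta["lat_step_arcsec"],
            meta["n_cols"],
            meta["n_rows"],
        )
        counts = pd.read_csv(p / "counts.csv", dtype={"taxon_id": str})
        months = pd.read_csv(p / "month_counts.csv", dtype={"taxon_id": str})
        if months.empty:
            months = pd.DataFrame(columns=cls.MONTH_COLS)
        return cls(grid, counts, months, meta.get("n_records", 0), meta.get("n_dated_records", 0))

    def total_mass(self) -> float:
        return float(self.counts["weight"].sum())

    def total_month_mass(self) -> float:
        return float(self.month_counts["weight"].sum()) if len(self.month_counts) else 0.0


def build_raster(records: list[PointOccurrence], grid: GridSpec) -> OccurrenceRaster:
    """Accumulate spatial (and, for dated records, spatio-temporal) weights.

    counts = Σ_records spatial_weights; month_counts = Σ over date-plausible
    records of the outer product spatial_weights ⊗ month_weights.
    """
    count_rows: list[tuple] = []
    month_rows: list[tuple] = []
    n_dated = 0
    for rec in records:
        sw = spatial_weights(rec, grid)
        for cell, w in sw.items():
            count_rows.append((cell.col, cell.row, rec.taxon_id, w))
        if rec.date_plausible and rec.event_date is not None:
            n_dated += 1
            mw = month_weights(rec.event_date)
            for cell, w in sw.items():
                for m, mwt in mw.items():
                    month_rows.append((cell.col, cell.row, rec.taxon_id, m, w * mwt))

    counts = pd.DataFrame(count_rows, columns=OccurrenceRaster.COUNT_COLS)
    if len(counts):
        counts = counts.groupby(["col", "row", "taxon_id"], as_index=False)["weight"].sum()
    months = pd.DataFrame(month_rows, columns=OccurrenceRaster.MONTH_COLS)
    if len(months):
        months = months.groupby(["col", "row", "taxon_id", "month"], as_index=False)["weight"].sum()
    return OccurrenceRaster(grid, counts, months, n_records=len(records), n_dated_records=n_dated)
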