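"""Scoring and ranking candidate taxa for a (location, date, radius) query.

Support for a taxon is the set of occupied unit centers — survey-tile centers
for the presence-absence source, computational-cell centers for the point
source — lying within the sampling radius r of the query location (closed
ball; r = 0 degenerates to the single containing unit). Five aggregation
strategies turn support into a score:

S1  relative frequency: mean of counts over the support;
S2  distance-weighted frequency: mean of counts/(1 + d/r);
S3  minimum distance: 1 − min d / max-support-distance;
S4  average distance: 1 − mean d / max-support-distance;
S5  phenology: Gaussian-weighted monthly mass centered on the query month.

All taxa with positive score form the candidate set, ordered by descending
score with lexicographic taxon-id tie-breaks. Scores from several maps (the
two data sources, or the S2 and S5 components of the combined strategy) are
merged by per-map max-normalisation followed by a weighted sum.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_grid import GeoPoint, GridSpec, OutOfRegionError, haversine_km
from .ingest import PresenceAbsenceDataset
from .rasterize import OccurrenceRaster

__all__ = [
    "Query",
    "ScoredTaxon",
    "RankedRecommendation",
    "RecommenderConfig",
    "Recommender",
    "combine",
    "STRATEGIES",
]

STRATEGIES = ("S1", "S2", "S3", "S4", "S5", "S2+S5")
SOURCES = ("grid", "points", "both")

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class Query:
    """One recommendation request: where, when, how far, and how to score."""

    p: GeoPoint
    date: _dt.date | None = None
    r_km: float = 0.0
    strategy: str = "S1"
    sources: str = "both"

    def __post_init__(self) -> None:
        if self.r_km < 0:
            raise ValueError("sampling radius must be non-negative")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.sources not in SOURCES:
            raise ValueError(f"unknown sources {self.sources!r}; expected one of {SOURCES}")
        if self.strategy in ("S5", "S2+S5") and self.date is None:
            raise ValueError(f"strategy {self.strategy} requires a query date")
        if self.strategy in ("S2", "S3", "S4", "S2+S5") and self.r_km <= 0:
            raise ValueError(f"strategy {self.strategy} aggregates multiple units and requires r > 0")


@dataclass(frozen=True)
class ScoredTaxon:
    taxon_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class RankedRecommendation:
    query: Query
    items: tuple[ScoredTaxon, ...]

    def taxa(self) -> list[str]:
        return [it.taxon_id for it in self.items]

    def rank_of(self, taxon_id: str) -> int | None:
        for it in self.items:
            if it.taxon_id == taxon_id:
                return it.rank
        return None

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(it.rank, it.taxon_id, it.score) for it in self.items],
            columns=["rank", "taxon_id", "score"],
        )


@dataclass(frozen=True)
class RecommenderConfig:
    """Tunable conventions left open by the scoring formulas.

    s34_normalizer: 'global' uses the maximum support distance over all taxa
    within r as the denominator of S3/S4 (a per-taxon maximum zeroes out every
    single-occurrence taxon); s5_circular wraps month distance at the year
    boundary; weights are (grid, points) and (S2, S5) respectively.
    """

    s34_normalizer: str = "global"  # or "per_taxon"
    s5_circular: bool = True
    source_weights: tuple[float, float] = (0.5, 0.5)
    strategy_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.s34_normalizer not in ("global", "per_taxon"):
            raise ValueError("s34_normalizer must be 'global' or 'per_taxon'")


def _normalize_map(scores: dict[str, float]) -> dict[str, float]:
    """Scale a non-negative score map onto [0, 1] by its maximum."""
    if not scores:
        return {}
    top = max(scores.values())
    if top <= 0:
        return {t: 0.0 for t in scores}
    return {t: s / top for t, s in scores.items()}


def combine(score_maps: list[dict[str, float]], weights: list[float]) -> dict[str, float]:
    """Weighted sum of per-map normalised scores; taxa absent from a map
    contribute 0 for it; only taxa with positive combined score are kept."""
    if len(score_maps) != len(weights):
        raise ValueError("one weight per score map required")
    if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
        raise ValueError("weights must be non-negative and not all zero")
    total_w = sum(weights)
    out: dict[str, float] = {}
    for m, w in zip(score_maps, weights):
        for t, s in _normalize_map(m).items():
            out[t] = out.get(t, 0.0) + w * s / total_w
    return {t: s for t, s in out.items() if s > 0}


def circular_month_distance(m1: int, m2: int) -> int:
    d = abs(m1 - m2)
    return min(d, 12 - d)


def _gauss(x: np.ndarray | float) -> np.ndarray | float:
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


class Recommender:
    """Query engine over a presence-absence dataset and/or occurrence raster."""

    def __init__(
        self,
        grid: GridSpec,
        presence: PresenceAbsenceDataset | None = None,
        raster: OccurrenceRaster | None = None,
        config: RecommenderConfig | None = None,
    ) -> None:
        self.grid = grid
        self.presence = presence
        self.raster = raster
        self.config = config or RecommenderConfig()
        self._pa = self._presence_table(presence) if presence is not None else None
        if raster is not None:
            self._counts = raster.counts
            self._months = raster.month_counts
        else:
            self._counts = self._months = None

    @staticmethod
    def _presence_table(presence: PresenceAbsenceDataset) -> pd.DataFrame:
        rows = []
        for tile_id, taxon in presence.presence:
            t = presence.tiles[tile_id]
            lon_min, lat_min, lon_max, lat_max = t.bounds
            rows.append((tile_id, taxon, t.center.lon, t.center.lat, lon_min, lat_min, lon_max, lat_max))
        return pd.DataFrame(
            rows,
            columns=["tile_id", "taxon_id", "lon", "lat", "lon_min", "lat_min", "lon_max", "lat_max"],
        )

    # ---------------------------------------------------------------- support

    def grid_support(self, p: GeoPoint, r_km: float) -> pd.DataFrame:
        """Occupied tile centers within r (or containing tiles at r = 0);
        columns taxon_id, dist_km, counts (binary source ⇒ counts = 1)."""
        if self._pa is None or self._pa.empty:
            return pd.DataFrame(columns=["taxon_id", "dist_km", "counts"])
        df = self._pa
        if r_km == 0:
            mask = (
                (df["lon_min"] <= p.lon)
                & (p.lon < df["lon_max"])
                & (df["lat_min"] <= p.lat)
                & (p.lat < df["lat_max"])
            )
            sub = df.loc[mask, ["taxon_id", "lon", "lat"]]
        else:
            d = haversine_km(p.lon, p.lat, df["lon"].to_numpy(), df["lat"].to_numpy())
            sub = df.loc[d <= r_km, ["taxon_id", "lon", "lat"]]
        if sub.empty:
            return pd.DataFrame(columns=["taxon_id", "dist_km", "counts"])
        dist = haversine_km(p.lon, p.lat, sub["lon"].to_numpy(), sub["lat"].to_numpy())
        return pd.DataFrame({"taxon_id": sub["taxon_id"].to_numpy(), "dist_km": dist, "counts": 1.0})

    def point_support(self, p: GeoPoint, r_km: float) -> pd.DataFrame:
        """Occupied cell centers within r (containing cell at r = 0); columns
        col, row, taxon_id, dist_km, counts."""
        empty = pd.DataFrame(columns=["col", "row", "taxon_id", "dist_km", "counts"])
        if self._counts is None or self._counts.empty:
            return empty
        if r_km == 0:
            cell = self.grid.locate(p)
            cells = pd.DataFrame({"col": [cell.col], "row": [cell.row]})
        else:
            cols, rows = self.grid.cells_within_km(p, r_km)
            if cols.size == 0:
                return empty
            cells = pd.DataFrame({"col": cols, "row": rows})
        sub = self._counts.merge(cells, on=["col", "row"], how="inner")
        if sub.empty:
            return empty
        lons, lats = self.grid.cell_center_arrays(sub["col"].to_numpy(), sub["row"].to_numpy())
        dist = haversine_km(p.lon, p.lat, lons, lats)
        return pd.DataFrame(
            {
                "col": sub["col"].to_numpy(),
                "row": sub["row"].to_numpy(),
                "taxon_id": sub["taxon_id"].to_numpy(),
                "dist_km": dist,
                "counts": sub["weight"].to_numpy(),
            }
        )

    def eligible_support(self, taxon_id: str, p: GeoPoint, r_km: float, source: str) -> pd.DataFrame:
        """The taxon's support set P^r within r for one source (inspection aid)."""
        sup = self.grid_support(p, r_km) if source == "grid" else self.point_support(p, r_km)
        return sup[sup["taxon_id"] == taxon_id].reset_index(drop=True)

    # ----------------------------------------------------------------- scores

    @staticmethod
    def score_s1(support: pd.DataFrame) -> dict[str, float]:
        if support.empty:
            return {}
        return support.groupby("taxon_id")["counts"].mean().to_dict()

    @staticmethod
    def score_s2(support: pd.DataFrame, r_km: float) -> dict[str, float]:
        if support.empty:
            return {}
        if r_km <= 0:
            raise ValueError("S2 requires r > 0")
        w = support["counts"] / (1.0 + support["dist_km"] / r_km)
        return w.groupby(support["taxon_id"]).mean().to_dict()

    def _s34_norms(self, support: pd.DataFrame) -> pd.Series:
        by_taxon_max = support.groupby("taxon_id")["dist_km"].max()
        if self.config.s34_normalizer == "global":
            return pd.Series(float(support["dist_km"].max()), index=by_taxon_max.index)
        return by_taxon_max

    def score_s3(self, support: pd.DataFrame) -> dict[str, float]:
        if support.empty:
            return {}
        mins = support.groupby("taxon_id")["dist_km"].min()
        norms = self._s34_norms(support)
        scores = (1.0 - mins / norms.replace(0.0, np.nan)).fillna(1.0).clip(0.0, 1.0)
        return scores.to_dict()

    def score_s4(self, support: pd.DataFrame) -> dict[str, float]:
        if support.empty:
            return {}
        means = support.groupby("taxon_id")["dist_km"].mean()
        norms = self._s34_norms(support)
        scores = (1.0 - means / norms.replace(0.0, np.nan)).fillna(1.0).clip(0.0, 1.0)
        return scores.to_dict()

    def score_s5(self, p: GeoPoint, r_km: float, date: _dt.date) -> dict[str, float]:
        """Phenology score from the per-month raster: for each supporting cell
        sum monthly mass weighted by a standard-normal kernel of the month
        distance to the query month, then average over the taxon's cells."""
        if self._months is None or self._months.empty:
            return {}
        if r_km == 0:
            cell = self.grid.locate(p)
            cells = pd.DataFrame({"col": [cell.col], "row": [cell.row]})
        else:
            cols, rows = self.grid.cells_within_km(p, r_km)
            if cols.size == 0:
                return {}
            cells = pd.DataFrame({"col": cols, "row": rows})
        sub = self._months.merge(cells, on=["col", "row"], how="inner")
        if sub.empty:
            return {}
        qm = date.month
        dm = np.abs(sub["month"].to_numpy() - qm)
        if self.config.s5_circular:
            dm = np.minimum(dm, 12 - dm)
        contrib = sub["weight"].to_numpy() * _gauss(dm.astype(float))
        per_cell = (
            pd.DataFrame({"taxon_id": sub["taxon_id"], "col": sub["col"], "row": sub["row"], "c": contrib})
            .groupby(["taxon_id", "col", "row"])["c"]
            .sum()
        )
        return per_cell.groupby("taxon_id").mean().to_dict()

    # ---------------------------------------------------------------- ranking

    def _source_map(self, strategy: str, source: str, query: Query) -> dict[str, float]:
        if strategy == "S5":
            if source == "grid":
                raise ValueError("S5 needs dated point records; the presence-absence source has no dates")
            return self.score_s5(query.p, query.r_km, query.date)
        support = self.grid_support(query.p, query.r_km) if source == "grid" else self.point_support(query.p, query.r_km)
        if strategy == "S1":
            return self.score_s1(support)
        if strategy == "S2":
            return self.score_s2(support, query.r_km)
        if strategy == "S3":
            return self.score_s3(support)
        if strategy == "S4":
            return self.score_s4(support)
        raise ValueError(f"unknown strategy {strategy!r}")

    def _component_map(self, strategy: str, query: Query) -> dict[str, float]:
        if strategy == "S5":
            if query.sources == "grid":
                raise ValueError("S5 needs dated point records; the presence-absence source has no dates")
            sources = ["points"]
        elif query.sources != "both":
            sources = [query.sources]
        else:
            sources = ["grid", "points"]
        maps = []
        for src in sources:
            if src == "grid" and self.presence is None:
                raise ValueError("query requests the grid source but no presence-absence data is loaded")
            if src == "points" and self.raster is None:
                raise ValueError("query requests the point source but no occurrence raster is loaded")
            maps.append(self._source_map(strategy, src, query))
        if len(maps) == 1:
            return {t: s for t, s in maps[0].items() if s > 0}
        return combine(maps, list(self.config.source_weights))

    def recommend(self, query: Query) -> RankedRecommendation:
        """Rank every taxon with positive score for the query (the candidate
        set), descending by score with ascending-taxon-id tie-breaks."""
        if not self.grid.contains(query.p):
            raise OutOfRegionError(f"query location ({query.p.lon}, {query.p.lat}) outside the study region")
        if query.strategy == "S2+S5":
            comp = [self._component_map("S2", query), self._component_map("S5", query)]
            scores = combine(comp, list(self.config.strategy_weights))
        else:
            scores = self._component_map(query.strategy, query)
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        items = tuple(ScoredTaxon(t, float(s), i + 1) for i, (t, s) in enumerate(ordered))
        return RankedRecommendation(query=query, items=items)
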