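"""Reading, sanitising and taxonomically harmonising the three delimited-text
inputs: presence-absence tiles, Darwin Core-style point occurrences, and
labeled test records.

Taxonomic harmonisation maps synonyms to accepted names and subsumes
sub-specific entries (subspecies, varieties, forms) under their species-level
parent before any counting, so that both data sources and the test set speak
the same taxon vocabulary. Unresolvable names are skipped and counted, never
fatal.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_grid import GeoPoint, GridSpec, Tile

logger = logging.getLogger(__name__)

DEFAULT_UNCERTAINTY_M = 500.0
UNCERTAINTY_CAP_M = 10_000.0

#: ranks treated as sub-specific and subsumed under their parent taxon
SUBSPECIFIC_RANKS = frozenset({"subspecies", "variety", "form", "forma"})

#: event dates treated as data-entry sentinels rather than real observations
SENTINEL_DATES = frozenset({_dt.date(1970, 1, 1)})
MIN_PLAUSIBLE_YEAR = 1700

VALID_STATUS = frozenset({"valid", "questionable", "false"})
VALID_PERIODS = frozenset({"pre1950", "1950to1980", "post1980"})


class IngestStats(dict):
    """Counter of kept/skipped rows per reason; input rows == sum of values."""

    def bump(self, reason: str, n: int = 1) -> None:
        self[reason] = self.get(reason, 0) + n

    def summary(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in sorted(self.items()))


@dataclass
class Taxonomy:
    """Accepted-name table with synonym and parent links.

    entries: taxon_id -> (accepted_name, parent_id, rank)
    """

    accepted: dict[str, dict]
    synonym_to_id: dict[str, str]
    name_to_id: dict[str, str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        accepted: dict[str, dict] = {}
        synonym_to_id: dict[str, str] = {}
        name_to_id: dict[str, str] = {}
        for row in df.itertuples(index=False):
            tid = str(row.taxon_id)
            if tid in accepted:
                raise ValueError(f"duplicate taxon_id {tid!r}")
            parent = getattr(row, "parent_id", None)
            parent = None if parent is None or (isinstance(parent, float) and np.isnan(parent)) or parent == "" else str(parent)
            rank = str(getattr(row, "rank", "species") or "species").lower()
            accepted[tid] = {"accepted_name": str(row.accepted_name), "parent_id": parent, "rank": rank}
            name_to_id[str(row.accepted_name)] = tid
            syns = getattr(row, "synonyms", "") or ""
            if isinstance(syns, float):
                syns = ""
            for syn in str(syns).split("|"):
                syn = syn.strip()
                if syn:
                    if syn in synonym_to_id and synonym_to_id[syn] != tid:
                        raise ValueError(f"synonym {syn!r} maps to more than one taxon")
                    synonym_to_id[syn] = tid
        tax = cls(accepted, synonym_to_id, name_to_id)
        tax._check_acyclic()
        return tax

    @classmethod
    def from_csv(cls, path) -> "Taxonomy":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def _check_acyclic(self) -> None:
        for tid in self.accepted:
            seen = {tid}
            cur = self.accepted[tid]["parent_id"]
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cyclic parent links at {tid!r}")
                seen.add(cur)
                cur = self.accepted.get(cur, {"parent_id": None})["parent_id"]

    def resolve(self, name_or_id: str) -> str | None:
        """Resolve a name/synonym/id to a species-level-or-above taxon id.

        Sub-specific entries climb parent links until reaching a rank at or
        above species. Unknown inputs return None.
        """
        key = str(name_or_id).strip()
        tid = None
        if key in self.accepted:
            tid = key
        elif key in self.name_to_id:
            tid = self.name_to_id[key]
        elif key in self.synonym_to_id:
            tid = self.synonym_to_id[key]
        if tid is None:
            return None
        hops = 0
        while self.accepted[tid]["rank"] in SUBSPECIFIC_RANKS and self.accepted[tid]["parent_id"]:
            parent = self.accepted[tid]["parent_id"]
            if parent not in self.accepted:
                break
            tid = parent
            hops += 1
            if hops > 20:  # defensive; _check_acyclic already ran
                break
        return tid

    def accepted_name(self, taxon_id: str) -> str:
        return self.accepted[taxon_id]["accepted_name"]

    def __len__(self) -> int:
        return len(self.accepted)


@dataclass(frozen=True)
class PointOccurrence:
    taxon_id: str
    location: GeoPoint
    event_date: _dt.date | None
    uncertainty_m: float
    date_plausible: bool

    def __post_init__(self) -> None:
        if self.uncertainty_m <= 0:
            raise ValueError("uncertainty_m must be positive")
        if self.date_plausible and self.event_date is None:
            raise ValueError("date_plausible requires an event_date")


@dataclass(frozen=True)
class TestRecord:
    location: GeoPoint
    date: _dt.date | None
    taxon_id: str


@dataclass
class PresenceAbsenceDataset:
    """Binary per-tile presence after status filtering and tile superseding.

    tiles: tile_id -> Tile; presence: set of (tile_id, taxon_id).
    """

    tiles: dict[str, Tile]
    presence: set[tuple[str, str]]
    stats: IngestStats = field(default_factory=IngestStats)

    _center_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def taxa(self) -> set[str]:
        return {t for _, t in self.presence}

    def taxa_in_tile(self, tile_id: str) -> set[str]:
        return {t for tid, t in self.presence if tid == tile_id}

    def occupied_centers(self):
        """(tile_ids, lons, lats) arrays over tiles carrying any presence."""
        if self._center_cache is None:
            ids = sorted({tid for tid, _ in self.presence})
            lons = np.array([self.tiles[t].center.lon for t in ids])
            lats = np.array([self.tiles[t].center.lat for t in ids])
            self._center_cache = (ids, lons, lats)
        return self._center_cache

    def presence_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tile_id": tid,
                "taxon_id": tax,
                "center_lon": self.tiles[tid].center.lon,
                "center_lat": self.tiles[tid].center.lat,
                "resolution_level": self.tiles[tid].resolution_level,
            }
            for tid, tax in sorted(self.presence)
        ]
        return pd.DataFrame(rows, columns=["tile_id", "taxon_id", "center_lon", "center_lat", "resolution_level"])


def _parse_date(value) -> _dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    # ISO 8601, possibly with a time part
    try:
        return _dt.date.fromisoformat(s[:10])
    except ValueError:
        return None


def _date_plausible(d: _dt.date | None, today: _dt.date | None = None) -> bool:
    if d is None:
        return False
    if d in SENTINEL_DATES:
        return False
    if d.year < MIN_PLAUSIBLE_YEAR:
        return False
    if d > (today or _dt.date.today()):
        return False
    return True


def _in_region(lon: float, lat: float, grid: GridSpec) -> bool:
    return (grid.origin.lon <= lon < grid.lon_max) and (grid.origin.lat <= lat < grid.lat_max)


def _read_delimited(path) -> pd.DataFrame:
    # sniff comma vs tab from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_presence_absence(path, taxonomy: Taxonomy, grid_region: GridSpec) -> PresenceAbsenceDataset:
    """Load presence-absence tiles, dropping questionable/false records and
    superseding full tiles by their quarter tiles per taxon.

    Where both a full tile and at least one of its quarter tiles record the
    same taxon, only the newer, higher-resolution quarter information is kept.
    """
    df = _read_delimited(path)
    stats = IngestStats()
    tiles: dict[str, Tile] = {}
    presence: set[tuple[str, str]] = set()

    for row in df.itertuples(index=False):
        try:
            status = str(row.status).strip().lower()
            if status not in VALID_STATUS:
                stats.bump("skipped_malformed")
                continue
            if status in ("questionable", "false"):
                stats.bump("skipped_status")
                continue
            lon, lat = float(row.center_lon), float(row.center_lat)
            if not _in_region(lon, lat, grid_region):
                stats.bump("skipped_out_of_region")
                continue
            level = str(row.resolution_level).strip().lower()
            tile = Tile(
                id=str(row.tile_id),
                center=GeoPoint(lon, lat),
                lon_extent_arcmin=float(row.lon_extent_arcmin),
                lat_extent_arcmin=float(row.lat_extent_arcmin),
                resolution_level=level,
            )
        except (ValueError, AttributeError):
            stats.bump("skipped_malformed")
            continue
        taxon = taxonomy.resolve(str(row.taxon))
        if taxon is None:
            stats.bump("skipped_unresolved_taxon")
            continue
        if tile.id in tiles and tiles[tile.id] != tile:
            stats.bump("skipped_malformed")  # conflicting geometry for one id
            continue
        tiles[tile.id] = tile
        if (tile.id, taxon) in presence:
            stats.bump("skipped_duplicate")
            continue
        presence.add((tile.id, taxon))
        stats.bump("kept")

    # superseding: drop a full-tile record when any quarter tile whose center
    # falls inside the full tile carries the same taxon
    full_tiles = {tid: t for tid, t in tiles.items() if t.resolution_level == "full"}
    if full_tiles:
        quarter_by_taxon: dict[str, list[str]] = {}
        for tid, tax in presence:
            if tiles[tid].resolution_level == "quarter":
                quarter_by_taxon.setdefault(tax, []).append(tid)
        to_drop = set()
        for tid, tax in presence:
            if tid not in full_tiles:
                continue
            full = full_tiles[tid]
            for qid in quarter_by_taxon.get(tax, ()):
                if full.contains(tiles[qid].center):
                    to_drop.add((tid, tax))
                    break
        for item in to_drop:
            presence.discard(item)
            stats.bump("superseded_full_tile")
            stats["kept"] -= 1

    if not presence:
        logger.warning("presence-absence file %s yielded no records (%s)", path, stats.summary())
    return PresenceAbsenceDataset(tiles=tiles, presence=presence, stats=stats)


def read_occurrences(
    path,
    taxonomy: Taxonomy,
    grid_region: GridSpec,
    uncertainty_cap_m: float = UNCERTAINTY_CAP_M,
    default_uncertainty_m: float = DEFAULT_UNCERTAINTY_M,
    today: _dt.date | None = None,
) -> tuple[list[PointOccurrence], IngestStats]:
    """Load Darwin Core-style point records, filtering implausible rows.

    Rows with missing/unparseable coordinates, out-of-region locations or
    uncertainty above the cap are dropped. Missing uncertainty falls back to
    the 500 m default. Sentinel dates (e.g. 1970-01-01) keep the record but
    flag it date-implausible so it never contributes phenology mass.
    """
    df = _read_delimited(path)
    taxon_col = "taxon" if "taxon" in df.columns else "scientificName"
    stats = IngestStats()
    out: list[PointOccurrence] = []

    for row in df.itertuples(index=False):
        try:
            lon = float(getattr(row, "decimalLongitude"))
            lat = float(getattr(row, "decimalLatitude"))
        except (ValueError, TypeError, AttributeError):
            stats.bump("skipped_bad_coordinates")
            continue
        if not (-180 <= lon <= 180 and -90 <= lat <= 90) or not _in_region(lon, lat, grid_region):
            stats.bump("skipped_out_of_region")
            continue
        unc_raw = str(getattr(row, "coordinateUncertaintyInMeters", "")).strip()
        if unc_raw == "":
            unc = default_uncertainty_m
        else:
            try:
                unc = float(unc_raw)
            except ValueError:
                stats.bump("skipped_bad_uncertainty")
                continue
            if unc <= 0:
                unc = default_uncertainty_m
        if unc > uncertainty_cap_m:
            stats.bump("skipped_poor_accuracy")
            continue
        taxon = taxonomy.resolve(str(getattr(row, taxon_col)))
        if taxon is None:
            stats.bump("skipped_unresolved_taxon")
            continue
        date = _parse_date(getattr(row, "eventDate", None))
        out.append(
            PointOccurrence(
                taxon_id=taxon,
                location=GeoPoint(lon, lat),
                event_date=date,
                uncertainty_m=unc,
                date_plausible=_date_plausible(date, today),
            )
        )
        stats.bump("kept")

    if not out:
        logger.warning("occurrence file %s yielded no records (%s)", path, stats.summary())
    return out, stats


def read_test_records(path, taxonomy: Taxonomy, grid_region: GridSpec | None = None) -> tuple[list[TestRecord], IngestStats]:
    """Load labeled (taxon, lon, lat, date) test queries; unresolved or
    out-of-region rows are skipped and counted."""
    df = _read_delimited(path)
    taxon_col = "taxon" if "taxon" in df.columns else "scientificName"
    stats = IngestStats()
    out: list[TestRecord] = []
    for row in df.itertuples(index=False):
        try:
            lon = float(getattr(row, "decimalLongitude"))
            lat = float(getattr(row, "decimalLatitude"))
        except (ValueError, TypeError, AttributeError):
            stats.bump("skipped_bad_coordinates")
            continue
        if grid_region is not None and not _in_region(lon, lat, grid_region):
            stats.bump("skipped_out_of_region")
            continue
        taxon = taxonomy.resolve(str(getattr(row, taxon_col)))
        if taxon is None:
            stats.bump("skipped_unresolved_taxon")
            continue
        out.append(TestRecord(location=GeoPoint(lon, lat), date=_parse_date(getattr(row, "eventDate", None)), taxon_id=taxon))
        stats.bump("kept")
    return out, stats


def resolve_taxon(name_or_id: str, taxonomy: Taxonomy) -> str | None:
    """Functional alias for Taxonomy.resolve."""
    return taxonomy.resolve(name_or_id)
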