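"""Self-contained synthetic landscapes with known ground truth.

The generator emulates the statistical structure of the three real inputs the
pipeline consumes — a floristic-atlas presence-absence export, a Darwin
Core-style occurrence download, and a labeled test set — without any download:

* each taxon occupies a circular range disc; its presence-absence tiles are
  exactly the survey tiles intersecting the disc;
* point records are drawn uniformly inside the disc with per-taxon expected
  abundance log-uniform across the configured bounds (a heavy imbalance, as in
  real aggregated occurrence archives), a wrapped phenology peak of
  configurable sharpness, a coordinate-uncertainty model with a configurable
  share of missing values, and a share of missing/sentinel event dates;
* a configurable fraction of taxa appears in both sources; the remainder is
  split between atlas-only and points-only taxa (mirroring e.g. garden plants
  absent from wildlife mapping);
* test records are drawn inside range discs at the taxon's phenology, with an
  optional label-corruption rate.

All randomness funnels through one seeded generator, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_grid import GeoPoint, GridSpec, Tile, haversine_km
from .ingest import PointOccurrence, PresenceAbsenceDataset, TestRecord, Taxonomy

__all__ = ["SyntheticConfig", "GroundTruth", "generate_landscape", "generate_test_records", "write_landscape"]

KM_PER_DEG_LAT = 111.0

_GENERA = (
    "Ranunculus", "Trifolium", "Campanula", "Veronica", "Galium", "Carex",
    "Silene", "Geranium", "Potentilla", "Euphorbia", "Viola", "Salvia",
)
_EPITHETS = (
    "albus", "montanus", "pratensis", "sylvaticus", "vernus", "palustris",
    "arvensis", "officinalis", "vulgaris", "minor", "major", "alpinus",
    "repens", "hirsutus", "glaber", "luteus", "niger", "ruber",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generated landscape; defaults are the study conditions
    every test and the acceptance script run under."""

    seed: int = 0
    n_taxa: int = 30
    region: tuple[float, float, float, float] = (10.0, 50.0, 12.0, 51.2)  # lon/lat bbox
    tile_extents_arcmin: tuple[float, float] = (10.0, 6.0)  # full tile; quarters are half
    n_records: int = 600
    range_radius_km: tuple[float, float] = (5.0, 25.0)  # log-uniform
    abundance_bounds: tuple[float, float] = (1.0, 50.0)  # expected records, log-uniform
    phenology_concentration: tuple[float, float] = (0.5, 4.0)  # von Mises-like kappa
    undated_fraction: float = 0.14
    missing_uncertainty_fraction: float = 0.65
    uncertainty_median_m: float = 300.0
    uncertainty_sigma: float = 0.7
    source_overlap: float = 1.0
    label_noise: float = 0.0
    n_test: int = 100
    synonym_fraction: float = 0.3
    subspecies_fraction: float = 0.2
    full_tile_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("undated_fraction", "missing_uncertainty_fraction", "source_overlap", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_taxa <= 0 or self.n_records <= 0:
            raise ValueError("n_taxa and n_records must be positive")
        lon_min, lat_min, lon_max, lat_max = self.region
        if lon_min >= lon_max or lat_min >= lat_max:
            raise ValueError("degenerate region bounding box")
        max_r_deg = self.range_radius_km[1] / KM_PER_DEG_LAT
        if (lat_max - lat_min) <= 2 * max_r_deg:
            raise ValueError("region too small for the largest range disc")


@dataclass
class GroundTruth:
    """What the generator knows: per-taxon disc, presence tiles, phenology,
    source membership, and (after test generation) the true test labels."""

    discs: dict[str, tuple[GeoPoint, float]]
    presence_tiles: dict[str, set[str]]
    phenology: dict[str, tuple[int, float]]  # (peak month, concentration)
    sources: dict[str, str]  # 'both' | 'grid' | 'points'
    records_per_taxon: dict[str, int]
    test_true_taxa: list[str] = field(default_factory=list)

    def grid_taxa(self) -> set[str]:
        return {t for t, s in self.sources.items() if s in ("grid", "both")}

    def point_taxa(self) -> set[str]:
        return {t for t, s in self.sources.items() if s in ("points", "both")}


def _taxon_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        g = _GENERA[i % len(_GENERA)]
        e = _EPITHETS[(i // len(_GENERA)) % len(_EPITHETS)]
        suffix = "" if i < len(_GENERA) * len(_EPITHETS) else f" {i}"
        names.append(f"{g} {e}{suffix}")
    return names


def _make_taxonomy(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[Taxonomy, list[str]]:
    names = _taxon_names(cfg.n_taxa)
    rows = []
    species_ids = []
    for i, name in enumerate(names):
        tid = f"t{i:04d}"
        species_ids.append(tid)
        syn = f"{name} auct." if rng.random() < cfg.synonym_fraction else ""
        rows.append({"taxon_id": tid, "accepted_name": name, "synonyms": syn, "parent_id": "", "rank": "species"})
    n_sub = int(round(cfg.subspecies_fraction * cfg.n_taxa))
    parents = rng.choice(cfg.n_taxa, size=n_sub, replace=False) if n_sub else []
    for j, pi in enumerate(parents):
        rows.append(
            {
                "taxon_id": f"s{j:04d}",
                "accepted_name": f"{names[pi]} subsp. minor",
                "synonyms": "",
                "parent_id": species_ids[pi],
                "rank": "subspecies",
            }
        )
    return Taxonomy.from_frame(pd.DataFrame(rows)), species_ids


def _tile_universe(cfg: SyntheticConfig) -> dict[str, Tile]:
    """Quarter tiles (plus the full-tile layer) covering the region."""
    lon_min, lat_min, lon_max, lat_max = cfg.region
    flon, flat = cfg.tile_extents_arcmin
    tiles: dict[str, Tile] = {}
    flon_deg, flat_deg = flon / 60.0, flat / 60.0
    n_fc = math.ceil((lon_max - lon_min) / flon_deg)
    n_fr = math.ceil((lat_max - lat_min) / flat_deg)
    for fc in range(n_fc):
        for fr in range(n_fr):
            west = lon_min + fc * flon_deg
            south = lat_min + fr * flat_deg
            tiles[f"F{fc:03d}_{fr:03d}"] = Tile(
                id=f"F{fc:03d}_{fr:03d}",
                center=GeoPoint(west + flon_deg / 2, south + flat_deg / 2),
                lon_extent_arcmin=flon,
                lat_extent_arcmin=flat,
                resolution_level="full",
            )
            for qc in range(2):
                for qr in range(2):
                    qid = f"Q{fc:03d}_{fr:03d}_{qc}{qr}"
                    tiles[qid] = Tile(
                        id=qid,
                        center=GeoPoint(
                            west + (qc + 0.5) * flon_deg / 2,
                            south + (qr + 0.5) * flat_deg / 2,
                        ),
                        lon_extent_arcmin=flon / 2,
                        lat_extent_arcmin=flat / 2,
                        resolution_level="quarter",
                    )
    return tiles


def _disc_intersects_tile(center: GeoPoint, radius_km: float, tile: Tile) -> bool:
    lon_min, lat_min, lon_max, lat_max = tile.bounds
    # closest point of the rectangle to the disc center, then exact distance
    clon = min(max(center.lon, lon_min), lon_max)
    clat = min(max(center.lat, lat_min), lat_max)
    return float(haversine_km(center.lon, center.lat, clon, clat)) <= radius_km


def _sample_in_disc(rng: np.random.Generator, center: GeoPoint, radius_km: float) -> GeoPoint:
    r = radius_km * math.sqrt(rng.random())
    theta = rng.random() * 2 * math.pi
    dlat = r * math.sin(theta) / KM_PER_DEG_LAT
    dlon = r * math.cos(theta) / (KM_PER_DEG_LAT * math.cos(math.radians(center.lat)))
    return GeoPoint(center.lon + dlon, center.lat + dlat)


def _month_probs(peak: int, kappa: float) -> np.ndarray:
    m = np.arange(1, 13)
    w = np.exp(kappa * np.cos(2 * math.pi * (m - peak) / 12.0))
    return w / w.sum()


def _sample_date(rng: np.random.Generator, peak: int, kappa: float, year_range=(1995, 2016)) -> _dt.date:
    month = int(rng.choice(12, p=_month_probs(peak, kappa))) + 1
    year = int(rng.integers(year_range[0], year_range[1] + 1))
    day = int(rng.integers(1, calendar.monthrange(year, month)[1] + 1))
    return _dt.date(year, month, day)


def generate_landscape(
    cfg: SyntheticConfig,
) -> tuple[Taxonomy, PresenceAbsenceDataset, list[PointOccurrence], GroundTruth]:
    """Build the full in-memory landscape; reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    taxonomy, species_ids = _make_taxonomy(cfg, rng)
    lon_min, lat_min, lon_max, lat_max = cfg.region

    # source membership: overlap fraction in both, remainder alternating
    n = len(species_ids)
    n_both = int(round(cfg.source_overlap * n))
    order = rng.permutation(n)
    sources: dict[str, str] = {}
    for j, idx in enumerate(order):
        tid = species_ids[idx]
        if j < n_both:
            sources[tid] = "both"
        else:
            sources[tid] = "grid" if (j - n_both) % 2 == 0 else "points"

    # range discs fully inside the region
    r_lo, r_hi = cfg.range_radius_km
    discs: dict[str, tuple[GeoPoint, float]] = {}
    phen: dict[str, tuple[int, float]] = {}
    for tid in species_ids:
        radius = float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
        pad_lat = radius / KM_PER_DEG_LAT
        mid_lat = (lat_min + lat_max) / 2
        pad_lon = radius / (KM_PER_DEG_LAT * math.cos(math.radians(mid_lat)))
        if lon_max - lon_min <= 2 * pad_lon or lat_max - lat_min <= 2 * pad_lat:
            raise ValueError("range disc does not fit inside the region")
        c = GeoPoint(
            float(rng.uniform(lon_min + pad_lon, lon_max - pad_lon)),
            float(rng.uniform(lat_min + pad_lat, lat_max - pad_lat)),
        )
        discs[tid] = (c, radius)
        phen[tid] = (int(rng.integers(1, 13)), float(rng.uniform(*cfg.phenology_concentration)))

    # presence-absence: tiles intersecting the disc, per grid-source taxon
    tiles = _tile_universe(cfg)
    quarter_tiles = {tid: t for tid, t in tiles.items() if t.resolution_level == "quarter"}
    full_tiles = {tid: t for tid, t in tiles.items() if t.resolution_level == "full"}
    presence: set[tuple[str, str]] = set()
    used_tiles: dict[str, Tile] = {}
    presence_tiles: dict[str, set[str]] = {t: set() for t in species_ids}
    for tid in species_ids:
        if sources[tid] == "points":
            continue
        center, radius = discs[tid]
        layer = full_tiles if rng.random() < cfg.full_tile_fraction else quarter_tiles
        for tile_id, tile in layer.items():
            if _disc_intersects_tile(center, radius, tile):
                presence.add((tile_id, tid))
                presence_tiles[tid].add(tile_id)
                used_tiles[tile_id] = tile
    pa = PresenceAbsenceDataset(tiles=used_tiles, presence=presence)

    # point records: every point-source taxon gets ≥1 record, the rest
    # multinomial with log-uniform expected abundance (heavy imbalance)
    point_taxa = [t for t in species_ids if sources[t] in ("points", "both")]
    records: list[PointOccurrence] = []
    rec_counts: dict[str, int] = {t: 0 for t in species_ids}
    if point_taxa:
        a_lo, a_hi = cfg.abundance_bounds
        weights = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=len(point_taxa)))
        n_extra = max(0, cfg.n_records - len(point_taxa))
        alloc = np.ones(len(point_taxa), dtype=int)
        if n_extra:
            alloc += rng.multinomial(n_extra, weights / weights.sum())
        for tid, k in zip(point_taxa, alloc):
            center, radius = discs[tid]
            peak, kappa = phen[tid]
            for _ in range(int(k)):
                loc = _sample_in_disc(rng, center, radius)
                u = rng.random()
                if u < cfg.undated_fraction / 2:
                    date, plaus = None, False
                elif u < cfg.undated_fraction:
                    date, plaus = _dt.date(1970, 1, 1), False  # sentinel default date
                else:
                    date, plaus = _sample_date(rng, peak, kappa), True
                if rng.random() < cfg.missing_uncertainty_fraction:
                    unc = 500.0  # ingest's default for records without the field
                else:
                    unc = float(
                        np.clip(
                            cfg.uncertainty_median_m * np.exp(rng.normal(0.0, cfg.uncertainty_sigma)),
                            20.0,
                            5000.0,
                        )
                    )
                records.append(
                    PointOccurrence(taxon_id=tid, location=loc, event_date=date, uncertainty_m=unc, date_plausible=plaus)
                )
            rec_counts[tid] = int(k)

    truth = GroundTruth(
        discs=discs,
        presence_tiles=presence_tiles,
        phenology=phen,
        sources=sources,
        records_per_taxon=rec_counts,
    )
    return taxonomy, pa, records, truth


def generate_test_records(cfg: SyntheticConfig, truth: GroundTruth) -> list[TestRecord]:
    """Labeled test queries drawn inside range discs at each taxon's phenology;
    labels corrupted at rate cfg.label_noise. Uses a seed stream disjoint from
    the landscape's."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    taxa = sorted(truth.discs)
    out: list[TestRecord] = []
    truth.test_true_taxa = []
    for _ in range(cfg.n_test):
        tid = taxa[int(rng.integers(len(taxa)))]
        center, radius = truth.discs[tid]
        peak, kappa = truth.phenology[tid]
        loc = _sample_in_disc(rng, center, radius)
        date = _sample_date(rng, peak, kappa, year_range=(2017, 2017))
        label = tid
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            others = [t for t in taxa if t != tid]
            label = others[int(rng.integers(len(others)))]
        truth.test_true_taxa.append(tid)
        out.append(TestRecord(location=loc, date=date, taxon_id=label))
    return out


def write_landscape(cfg: SyntheticConfig, out_dir) -> GroundTruth:
    """Write the four standard input files (taxa.csv, presence.csv,
    occurrences.csv, test.csv) exactly as the ingest module reads them.

    A few questionable/false presence rows and synonym-labeled occurrence rows
    are injected so ingest's filters are exercised; they are filtered back out
    on reading, so a round trip reproduces the in-memory landscape.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    taxonomy, pa, records, truth = generate_landscape(cfg)
    tests = generate_test_records(cfg, truth)

    tax_rows = []
    for tid, entry in sorted(taxonomy.accepted.items()):
        syns = "|".join(sorted(s for s, t in taxonomy.synonym_to_id.items() if t == tid))
        tax_rows.append(
            {
                "taxon_id": tid,
                "accepted_name": entry["accepted_name"],
                "synonyms": syns,
                "parent_id": entry["parent_id"] or "",
                "rank": entry["rank"],
            }
        )
    pd.DataFrame(tax_rows).to_csv(out / "taxa.csv", index=False)

    pa_rows = []
    for tile_id, taxon in sorted(pa.presence):
        t = pa.tiles[tile_id]
        pa_rows.append(
            {
                "tile_id": tile_id,
                "center_lon": round(t.center.lon, 8),
                "center_lat": round(t.center.lat, 8),
                "lon_extent_arcmin": t.lon_extent_arcmin,
                "lat_extent_arcmin": t.lat_extent_arcmin,
                "resolution_level": t.resolution_level,
                "taxon": taxonomy.accepted_name(taxon),
                "status": "valid",
                "period": "post1980",
            }
        )
    # a couple of rows ingest must drop
    if pa_rows:
        for status in ("questionable", "false"):
            bad = dict(pa_rows[int(rng.integers(len(pa_rows)))])
            bad["status"] = status
            pa_rows.append(bad)
    pd.DataFrame(pa_rows).to_csv(out / "presence.csv", index=False)

    syn_by_id: dict[str, str] = {}
    for s, t in taxonomy.synonym_to_id.items():
        syn_by_id.setdefault(t, s)
    occ_rows = []
    for rec in records:
        name = taxonomy.accepted_name(rec.taxon_id)
        if rec.taxon_id in syn_by_id and rng.random() < 0.3:
            name = syn_by_id[rec.taxon_id]
        unc = "" if rec.uncertainty_m == 500.0 else repr(rec.uncertainty_m)
        occ_rows.append(
            {
                "taxon": name,
                "decimalLongitude": round(rec.location.lon, 8),
                "decimalLatitude": round(rec.location.lat, 8),
                "eventDate": rec.event_date.isoformat() if rec.event_date else "",
                "coordinateUncertaintyInMeters": unc,
            }
        )
    pd.DataFrame(occ_rows).to_csv(out / "occurrences.csv", index=False)

    test_rows = [
        {
            "taxon": taxonomy.accepted_name(tr.taxon_id),
            "decimalLongitude": round(tr.location.lon, 8),
            "decimalLatitude": round(tr.location.lat, 8),
            "eventDate": tr.date.isoformat() if tr.date else "",
        }
        for tr in tests
    ]
    pd.DataFrame(test_rows).to_csv(out / "test.csv", index=False)
    return truth
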