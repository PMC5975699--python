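"""Naive full-scan reference scorer, independent of the package internals.

Everything is recomputed from raw inputs with plain Python loops: its own
haversine, brute-force kernel rasterization over every cell center, explicit
per-taxon support scans and literal transcriptions of the scoring formulas.
Used to cross-check ranked recommendations on small random instances.
"""

from __future__ import annotations

import calendar
import math

R_EARTH = 6371.0
SQRT_2PI = math.sqrt(2 * math.pi)


def hav_km(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * R_EARTH * math.asin(min(1.0, math.sqrt(a)))


class OracleGrid:
    def __init__(self, origin_lon, origin_lat, lon_step_deg, lat_step_deg, n_cols, n_rows):
        self.o_lon, self.o_lat = origin_lon, origin_lat
        self.dlon, self.dlat = lon_step_deg, lat_step_deg
        self.n_cols, self.n_rows = n_cols, n_rows

    def center(self, c, r):
        return (self.o_lon + (c + 0.5) * self.dlon, self.o_lat + (r + 0.5) * self.dlat)

    def locate(self, lon, lat):
        c = min(int((lon - self.o_lon) / self.dlon), self.n_cols - 1)
        r = min(int((lat - self.o_lat) / self.dlat), self.n_rows - 1)
        return c, r

    def all_cells(self):
        for c in range(self.n_cols):
            for r in range(self.n_rows):
                yield c, r


def oracle_spatial_weights(lon, lat, unc_m, grid: OracleGrid):
    """Linear-decay kernel over every cell center, renormalized to unit mass."""
    u_km = unc_m / 1000.0
    raw = {}
    for c, r in grid.all_cells():
        clon, clat = grid.center(c, r)
        d = hav_km(lon, lat, clon, clat)
        w = max(0.0, 1.0 - d / u_km)
        if w > 0:
            raw[(c, r)] = w
    total = sum(raw.values())
    if total <= 0:
        return {grid.locate(lon, lat): 1.0}
    return {cell: w / total for cell, w in raw.items()}


def oracle_month_weights(date):
    dim = calendar.monthrange(date.year, date.month)[1]
    mid = math.ceil((dim + 1) / 2)
    off = date.day - mid
    if off == 0:
        return {date.month: 1.0}
    own = 1.0 - abs(off) / dim
    other = (date.month + (1 if off > 0 else -1) - 1) % 12 + 1
    return {date.month: own, other: 1.0 - own}


def oracle_rasterize(records, grid: OracleGrid):
    """records: (taxon, lon, lat, unc_m, date_or_None, date_plausible)."""
    counts, months = {}, {}
    for taxon, lon, lat, unc, date, plausible in records:
        sw = oracle_spatial_weights(lon, lat, unc, grid)
        for cell, w in sw.items():
            counts[(cell, taxon)] = counts.get((cell, taxon), 0.0) + w
        if plausible and date is not None:
            for m, mw in oracle_month_weights(date).items():
                for cell, w in sw.items():
                    key = (cell, taxon, m)
                    months[key] = months.get(key, 0.0) + w * mw
    return counts, months


def _point_support(counts, grid, taxon, p_lon, p_lat, r_km):
    """[(dist_km, count)] over the taxon's occupied cells within r."""
    sup = []
    if r_km == 0:
        home = grid.locate(p_lon, p_lat)
        if (home, taxon) in counts and counts[(home, taxon)] > 0:
            clon, clat = grid.center(*home)
            sup.append((hav_km(p_lon, p_lat, clon, clat), counts[(home, taxon)], home))
        return sup
    for (cell, t), cnt in counts.items():
        if t != taxon or cnt <= 0:
            continue
        clon, clat = grid.center(*cell)
        d = hav_km(p_lon, p_lat, clon, clat)
        if d <= r_km:
            sup.append((d, cnt, cell))
    return sup


def _grid_tile_support(tiles, taxon, p_lon, p_lat, r_km):
    """tiles: (taxon, center_lon, center_lat, (lon_min, lat_min, lon_max, lat_max))."""
    sup = []
    for t, clon, clat, bounds in tiles:
        if t != taxon:
            continue
        if r_km == 0:
            lon_min, lat_min, lon_max, lat_max = bounds
            if lon_min <= p_lon < lon_max and lat_min <= p_lat < lat_max:
                sup.append((hav_km(p_lon, p_lat, clon, clat), 1.0, None))
        else:
            d = hav_km(p_lon, p_lat, clon, clat)
            if d <= r_km:
                sup.append((d, 1.0, None))
    return sup


def _scores_s1_to_s4(support_by_taxon, strategy, r_km, s34_normalizer):
    scores = {}
    if strategy in ("S3", "S4") and s34_normalizer == "global":
        all_d = [d for sup in support_by_taxon.values() for d, _, _ in sup]
        global_max = max(all_d) if all_d else 0.0
    for taxon, sup in support_by_taxon.items():
        if not sup:
            continue
        if strategy == "S1":
            s = sum(c for _, c, _ in sup) / len(sup)
        elif strategy == "S2":
            s = sum(c / (1.0 + d / r_km) for d, c, _ in sup) / len(sup)
        else:
            norm = global_max if s34_normalizer == "global" else max(d for d, _, _ in sup)
            if strategy == "S3":
                s = 1.0 if norm == 0 else 1.0 - min(d for d, _, _ in sup) / norm
            else:
                s = 1.0 if norm == 0 else 1.0 - (sum(d for d, _, _ in sup) / len(sup)) / norm
            s = min(1.0, max(0.0, s))
        scores[taxon] = s
    return scores


def _scores_s5(months, grid, taxa, p_lon, p_lat, r_km, month_q, circular):
    scores = {}
    for taxon in taxa:
        cells = {}
        for (cell, t, m), w in months.items():
            if t != taxon or w <= 0:
                continue
            if r_km == 0:
                if cell != grid.locate(p_lon, p_lat):
                    continue
            else:
                clon, clat = grid.center(*cell)
                if hav_km(p_lon, p_lat, clon, clat) > r_km:
                    continue
            dm = abs(m - month_q)
            if circular:
                dm = min(dm, 12 - dm)
            phi = math.exp(-0.5 * dm * dm) / SQRT_2PI
            cells[cell] = cells.get(cell, 0.0) + w * phi
        if cells:
            scores[taxon] = sum(cells.values()) / len(cells)
    return scores


def _normalize(m):
    if not m:
        return {}
    top = max(m.values())
    if top <= 0:
        return {t: 0.0 for t in m}
    return {t: v / top for t, v in m.items()}


def _combine(maps, weights):
    total = sum(weights)
    out = {}
    for m, w in zip(maps, weights):
        for t, v in _normalize(m).items():
            out[t] = out.get(t, 0.0) + w * v / total
    return {t: v for t, v in out.items() if v > 0}


def oracle_recommend(
    p_lon,
    p_lat,
    date,
    r_km,
    strategy,
    sources,
    grid: OracleGrid,
    records,
    tiles,
    taxa,
    s34_normalizer="global",
    s5_circular=True,
    source_weights=(0.5, 0.5),
    strategy_weights=(0.5, 0.5),
):
    """Full-scan ranked list [(taxon, score, rank)]; ties by ascending taxon."""
    counts, months = oracle_rasterize(records, grid)

    def source_map(strat, source):
        if strat == "S5":
            return _scores_s5(months, grid, taxa, p_lon, p_lat, r_km, date.month, s5_circular)
        support = {}
        for taxon in taxa:
            sup = (
                _grid_tile_support(tiles, taxon, p_lon, p_lat, r_km)
                if source == "grid"
                else _point_support(counts, grid, taxon, p_lon, p_lat, r_km)
            )
            if sup:
                support[taxon] = sup
        return _scores_s1_to_s4(support, strat, r_km, s34_normalizer)

    def component(strat):
        if strat == "S5":
            return {t: s for t, s in source_map("S5", "points").items() if s > 0}
        if sources == "both":
            return _combine([source_map(strat, "grid"), source_map(strat, "points")], list(source_weights))
        return {t: s for t, s in source_map(strat, sources).items() if s > 0}

    if strategy == "S2+S5":
        scores = _combine([component("S2"), component("S5")], list(strategy_weights))
    else:
        scores = component(strategy)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(t, s, i + 1) for i, (t, s) in enumerate(ranked)]
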