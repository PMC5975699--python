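"""Scoring strategies, score-map combination, and ranked recommendation."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from florarec import (
    GeoPoint,
    GridSpec,
    PointOccurrence,
    PresenceAbsenceDataset,
    Query,
    Recommender,
    RecommenderConfig,
    Tile,
    build_raster,
    combine,
)
from florarec.geo_grid import OutOfRegionError
from _oracle import oracle_recommend
from conftest import make_instance, make_query

SQRT_2PI = math.sqrt(2 * math.pi)


def _support(rows):
    return pd.DataFrame(rows, columns=["taxon_id", "dist_km", "counts"])


def _recommender(**cfg):
    grid = GridSpec(GeoPoint(10.0, 50.0), 30.0, 18.0, 20, 20)
    return Recommender(grid, config=RecommenderConfig(**cfg))


class TestScoreFormulas:
    def test_s1_is_mean_of_counts(self):
        rec = _recommender()
        assert rec.score_s1(_support([("a", 0.0, 3.0)])) == {"a": 3.0}
        assert rec.score_s1(_support([("a", 1.0, 2.0), ("a", 2.0, 4.0)]))["a"] == pytest.approx(3.0)

    def test_s2_equals_s1_at_zero_distance(self):
        sup = _support([("a", 0.0, 2.0), ("a", 0.0, 4.0)])
        rec = _recommender()
        assert rec.score_s2(sup, 5.0)["a"] == pytest.approx(rec.score_s1(sup)["a"])

    def test_s2_halves_counts_at_the_radius(self):
        # a single support location with counts 2 at distance exactly r scores 2/(1+1)=1
        rec = _recommender()
        assert rec.score_s2(_support([("a", 5.0, 2.0)]), 5.0)["a"] == pytest.approx(1.0)

    def test_s2_never_exceeds_s1(self):
        rng = np.random.default_rng(0)
        sup = _support([("a", float(rng.uniform(0, 5)), float(rng.uniform(0.5, 3))) for _ in range(10)])
        rec = _recommender()
        assert rec.score_s2(sup, 5.0)["a"] <= rec.score_s1(sup)["a"]

    def test_s3_global_normalizer(self):
        # taxon a: min distance 1; global max over all support = 4 -> 1 - 1/4
        sup = _support([("a", 1.0, 1.0), ("a", 3.0, 1.0), ("b", 4.0, 1.0)])
        scores = _recommender().score_s3(sup)
        assert scores["a"] == pytest.approx(0.75)
        assert scores["b"] == pytest.approx(0.0)

    def test_s3_nearest_at_zero_scores_one(self):
        sup = _support([("a", 0.0, 1.0), ("b", 2.0, 1.0)])
        assert _recommender().score_s3(sup)["a"] == pytest.approx(1.0)

    def test_s3_per_taxon_normalizer_option(self):
        sup = _support([("a", 1.0, 1.0), ("a", 3.0, 1.0), ("b", 4.0, 1.0)])
        scores = _recommender(s34_normalizer="per_taxon").score_s3(sup)
        assert scores["a"] == pytest.approx(1 - 1 / 3)
        assert scores["b"] == pytest.approx(0.0)  # single-support taxon: min == max

    def test_s4_mean_distance(self):
        sup = _support([("a", 2.0, 1.0), ("a", 4.0, 1.0)])
        assert _recommender().score_s4(sup)["a"] == pytest.approx(0.25)  # 1 - 3/4

    def test_s34_all_support_at_query_defaults_to_one(self):
        sup = _support([("a", 0.0, 1.0)])
        rec = _recommender()
        assert rec.score_s3(sup)["a"] == 1.0
        assert rec.score_s4(sup)["a"] == 1.0


class TestS5:
    def _raster_with_month_mass(self, month, taxon="a"):
        grid = GridSpec(GeoPoint(10.0, 50.0), 30.0, 18.0, 20, 20)
        center = grid.cell_center(type(grid.locate(GeoPoint(10.05, 50.05)))(5, 5))
        mid_day = 15 if month == 2 else 16  # mid-month day: single bin
        rec = PointOccurrence(taxon, center, dt.date(2015, month, mid_day), 50.0, True)
        raster = build_raster([rec], grid)
        return Recommender(grid, raster=raster), center

    def test_unit_mass_in_query_month(self):
        rec, p = self._raster_with_month_mass(6)
        scores = rec.score_s5(p, 1.0, dt.date(2017, 6, 15))
        assert scores["a"] == pytest.approx(1 / SQRT_2PI, abs=1e-9)

    def test_unit_mass_one_month_away(self):
        rec, p = self._raster_with_month_mass(5)
        scores = rec.score_s5(p, 1.0, dt.date(2017, 6, 15))
        assert scores["a"] == pytest.approx(math.exp(-0.5) / SQRT_2PI, abs=1e-9)

    def test_december_january_wraps_circularly(self):
        rec, p = self._raster_with_month_mass(12)
        scores = rec.score_s5(p, 1.0, dt.date(2017, 1, 15))
        assert scores["a"] == pytest.approx(math.exp(-0.5) / SQRT_2PI, abs=1e-9)

    def test_non_circular_option(self):
        grid = GridSpec(GeoPoint(10.0, 50.0), 30.0, 18.0, 20, 20)
        center = grid.cell_center(grid.locate(GeoPoint(10.05, 50.05)))
        rec_obj = PointOccurrence("a", center, dt.date(2015, 12, 16), 50.0, True)
        raster = build_raster([rec_obj], grid)
        rec = Recommender(grid, raster=raster, config=RecommenderConfig(s5_circular=False))
        scores = rec.score_s5(center, 1.0, dt.date(2017, 1, 15))
        assert scores["a"] == pytest.approx(math.exp(-0.5 * 121) / SQRT_2PI, abs=1e-12)


class TestCombine:
    def test_single_map_preserves_ranking(self):
        m = {"a": 4.0, "b": 2.0, "c": 1.0}
        out = combine([m], [1.0])
        assert sorted(out, key=out.get, reverse=True) == ["a", "b", "c"]
        assert set(out) == set(m)

    def test_taxon_absent_from_one_of_two_maps(self):
        out = combine([{"a": 3.0}, {"b": 7.0}], [0.5, 0.5])
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(0.5)

    def test_equal_normalized_scores_pass_through(self):
        out = combine([{"a": 2.0, "b": 4.0}, {"a": 1.0, "b": 2.0}], [0.5, 0.5])
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(1.0)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            combine([{"a": 1.0}], [0.0])
        with pytest.raises(ValueError):
            combine([{"a": 1.0}, {"b": 1.0}], [1.0])


class TestQueryValidation:
    def test_strategies_needing_radius_reject_zero(self):
        for strat in ("S2", "S3", "S4", "S2+S5"):
            with pytest.raises(ValueError, match="r > 0"):
                Query(GeoPoint(10, 50), dt.date(2017, 6, 1), 0.0, strat, "points")

    def test_s5_requires_date(self):
        with pytest.raises(ValueError, match="date"):
            Query(GeoPoint(10, 50), None, 5.0, "S5", "points")

    def test_s5_on_grid_source_rejected(self):
        rec = _recommender()
        q = Query(GeoPoint(10.05, 50.05), dt.date(2017, 6, 1), 5.0, "S5", "grid")
        with pytest.raises(ValueError, match="S5"):
            rec.recommend(q)

    def test_out_of_region_query(self):
        rec = _recommender()
        with pytest.raises(OutOfRegionError):
            rec.recommend(Query(GeoPoint(15.0, 55.0), None, 1.0, "S1", "points"))


def _build_recommender(inst, **cfg):
    raster = build_raster(inst.records, inst.grid)
    return Recommender(inst.grid, presence=inst.presence, raster=raster, config=RecommenderConfig(**cfg))


class TestRecommend:
    def test_zero_scores_excluded_and_ranks_dense(self):
        inst = make_instance(3)
        rec = _build_recommender(inst)
        p, date, r = make_query(3, inst)
        out = rec.recommend(Query(p, date, r, "S1", "both"))
        assert all(it.score > 0 for it in out.items)
        assert [it.rank for it in out.items] == list(range(1, len(out) + 1))
        scores = [it.score for it in out.items]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_ties_broken_lexicographically(self):
        # binary grid data: all present taxa score 1 under S1 -> pure lexicographic order
        inst = make_instance(5)
        rec = _build_recommender(inst)
        p, date, r = make_query(5, inst)
        out = rec.recommend(Query(p, date, 10.0, "S1", "grid"))
        groups = {}
        for it in out.items:
            groups.setdefault(round(it.score, 12), []).append(it.taxon_id)
        for taxa in groups.values():
            assert taxa == sorted(taxa)

    def test_binary_grid_source_ties_under_s1(self):
        # with a radius capturing tiles, every present taxon has identical S1 score
        inst = make_instance(8)
        rec = _build_recommender(inst)
        p, date, _ = make_query(8, inst)
        out = rec.recommend(Query(p, date, 50.0, "S1", "grid"))
        if len(out) > 1:
            assert len({round(it.score, 12) for it in out.items}) == 1

    @pytest.mark.parametrize("strategy,sources", [("S1", "points"), ("S2", "both"), ("S5", "points"), ("S2+S5", "both")])
    def test_candidate_sets_monotone_in_radius(self, strategy, sources):
        inst = make_instance(13)
        rec = _build_recommender(inst)
        p, date, _ = make_query(13, inst)
        radii = [0.5, 1.5, 3.0, 8.0]
        prev = set()
        for r in radii:
            taxa = set(rec.recommend(Query(p, date, r, strategy, sources)).taxa())
            assert prev <= taxa
            prev = taxa

    def test_scale_invariance_of_rankings(self):
        # multiplying all raw counts by a constant preserves S1/S2/S5 rankings
        inst = make_instance(17)
        raster = build_raster(inst.records, inst.grid)
        scaled = raster.counts.copy()
        scaled["weight"] *= 37.0
        smonths = raster.month_counts.copy()
        smonths["weight"] *= 37.0
        r1 = Recommender(inst.grid, presence=inst.presence, raster=raster)
        r2 = Recommender(
            inst.grid, presence=inst.presence, raster=type(raster)(inst.grid, scaled, smonths, raster.n_records, raster.n_dated_records)
        )
        p, date, r = make_query(17, inst)
        for strategy in ("S1", "S2", "S5"):
            a = r1.recommend(Query(p, date, max(r, 1.0), strategy, "points")).taxa()
            b = r2.recommend(Query(p, date, max(r, 1.0), strategy, "points")).taxa()
            assert a == b

    def test_eligible_support_exact_cell_at_zero_radius(self):
        inst = make_instance(21)
        rec = _build_recommender(inst)
        # pick a record and query its own location at r = 0
        target = inst.records[0]
        sup = rec.point_support(target.location, 0.0)
        home = inst.grid.locate(target.location)
        assert set(zip(sup["col"], sup["row"])) <= {(home.col, home.row)}


ALL_COMBOS = [
    ("S1", "grid"), ("S1", "points"), ("S1", "both"),
    ("S2", "grid"), ("S2", "points"), ("S2", "both"),
    ("S3", "points"), ("S3", "both"),
    ("S4", "points"), ("S4", "grid"),
    ("S5", "points"), ("S5", "both"),
    ("S2+S5", "points"), ("S2+S5", "both"),
]


def assert_matches_oracle(inst, p, date, r_km, strategy, sources):
    rec = _build_recommender(inst)
    got = rec.recommend(Query(p, date, r_km, strategy, sources))
    expected = oracle_recommend(
        p.lon, p.lat, date, r_km, strategy, sources,
        inst.oracle_grid, inst.oracle_records, inst.oracle_tiles, inst.taxa,
    )
    exp_scores = {t: s for t, s, _ in expected}
    got_scores = {it.taxon_id: it.score for it in got.items}
    assert set(got_scores) == set(exp_scores)
    for t, s in exp_scores.items():
        assert got_scores[t] == pytest.approx(s, abs=1e-9), (t, strategy, sources)
    # rank agreement wherever scores are not numerically tied
    exp_rank = {t: r for t, _, r in expected}
    for it in got.items:
        ties = [u for u, s in exp_scores.items() if abs(s - got_scores[it.taxon_id]) < 1e-9]
        if len(ties) == 1:
            assert it.rank == exp_rank[it.taxon_id]


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_random_instances(seed):
    """Full pipeline (rasterize + support + scores + combination + ranking)
    agrees with the naive full-scan scorer on random small instances."""
    inst = make_instance(seed)
    p, date, r_km = make_query(seed, inst)
    strategy, sources = ALL_COMBOS[seed % len(ALL_COMBOS)]
    assert_matches_oracle(inst, p, date, r_km, strategy, sources)


def test_oracle_equivalence_zero_radius():
    inst = make_instance(100, max_records=30)
    target = inst.records[0]
    for strategy, sources in [("S1", "points"), ("S1", "grid"), ("S1", "both"), ("S5", "points")]:
        assert_matches_oracle(inst, target.location, dt.date(2017, 6, 15), 0.0, strategy, sources)
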