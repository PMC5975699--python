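"""Ranked-retrieval evaluation: completeness and compactness metrics over a
labeled test set, k-fold cross-validation on point records, and a
grid-resolution sweep.

Five metrics summarise a set of N ranked candidate lists:

* R     — average recall: fraction of queries whose labeled taxon appears
          anywhere on its list; R_k truncates lists at rank k first.
* LL    — average list length.
* LR    — average list reduction: (|T|/N) Σ 1/|T_n|, the mean factor by which
          the candidate list shrinks the full taxa universe.
* MRR   — mean reciprocal rank, 0 for misses.
* M     — median rank: smallest rank position by which at least half of the
          retrieved correct taxa have appeared (misses excluded).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_grid import GridSpec, OutOfRegionError
from .ingest import PointOccurrence, PresenceAbsenceDataset, TestRecord
from .rasterize import build_raster
from .recommend import Query, Recommender, RecommenderConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PerQuery",
    "EvaluationReport",
    "FoldPlan",
    "QueryTemplate",
    "recall_at",
    "list_metrics",
    "mrr",
    "median_rank",
    "evaluate",
    "cross_validate",
    "resolution_sweep",
]

DEFAULT_KS = (20, 514)


@dataclass(frozen=True)
class PerQuery:
    """Outcome of one test query: rank of the labeled taxon (None = miss) and
    the candidate-list length."""

    n: int
    rank: int | None
    list_len: int


@dataclass(frozen=True)
class QueryTemplate:
    """The query parameters shared by every test record in an experiment."""

    r_km: float
    strategy: str = "S1"
    sources: str = "both"


def recall_at(per_query: list[PerQuery], k: float) -> float:
    """Fraction of queries whose labeled taxon ranks ≤ k (misses count 0)."""
    if not per_query:
        raise ValueError("empty test set")
    hits = sum(1 for q in per_query if q.rank is not None and q.rank <= k)
    return hits / len(per_query)


def list_metrics(per_query: list[PerQuery], total_taxa: int) -> tuple[float, float]:
    """(LL, LR). Empty candidate lists are excluded from the LR mean (its
    harmonic term is undefined at length 0) with a logged warning."""
    if not per_query:
        raise ValueError("empty test set")
    ll = float(np.mean([q.list_len for q in per_query]))
    nonempty = [q.list_len for q in per_query if q.list_len > 0]
    if len(nonempty) < len(per_query):
        logger.warning("%d empty candidate lists excluded from LR", len(per_query) - len(nonempty))
    lr = float(total_taxa / len(nonempty) * np.sum([1.0 / L for L in nonempty])) if nonempty else float("nan")
    return ll, lr


def mrr(per_query: list[PerQuery]) -> float:
    """Mean reciprocal rank; a missed taxon contributes 0."""
    if not per_query:
        raise ValueError("empty test set")
    return float(np.mean([1.0 / q.rank if q.rank is not None else 0.0 for q in per_query]))


def median_rank(per_query: list[PerQuery]) -> int | None:
    """Smallest rank s such that at least half of the *retrieved* correct taxa
    rank ≤ s; None when no query retrieved its taxon."""
    ranks = sorted(q.rank for q in per_query if q.rank is not None)
    if not ranks:
        return None
    half = len(ranks) / 2.0
    cum = 0
    for i, r in enumerate(ranks):
        cum = i + 1
        if cum >= half:
            return r
    return ranks[-1]


@dataclass
class EvaluationReport:
    """All five metrics plus the per-query table they were computed from."""

    n: int
    R: float
    R_at: dict[int, float]
    LL: float
    LR: float
    MRR: float
    M: int | None
    per_query: list[PerQuery] = field(repr=False, default_factory=list)
    total_taxa: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "R": self.R,
            "R_at": {str(k): v for k, v in self.R_at.items()},
            "LL": self.LL,
            "LR": self.LR,
            "MRR": self.MRR,
            "M": self.M,
            "total_taxa": self.total_taxa,
            **({"meta": self.meta} if self.meta else {}),
        }

    @classmethod
    def from_per_query(
        cls, per_query: list[PerQuery], total_taxa: int, ks=DEFAULT_KS, meta: dict | None = None
    ) -> "EvaluationReport":
        ll, lr = list_metrics(per_query, total_taxa)
        return cls(
            n=len(per_query),
            R=recall_at(per_query, float("inf")),
            R_at={int(k): recall_at(per_query, k) for k in ks},
            LL=ll,
            LR=lr,
            MRR=mrr(per_query),
            M=median_rank(per_query),
            per_query=per_query,
            total_taxa=total_taxa,
            meta=meta or {},
        )


def evaluate(
    test_records: list[TestRecord],
    template: QueryTemplate,
    recommender: Recommender,
    total_taxa: int | None = None,
    ks=DEFAULT_KS,
) -> EvaluationReport:
    """Run one recommendation per test record and aggregate all metrics.

    Out-of-region queries count as misses with an empty list (warning logged).
    Deterministic given inputs; invariant to test-set order up to the
    per-query table's own ordering.
    """
    if total_taxa is None:
        taxa = set()
        if recommender.presence is not None:
            taxa |= recommender.presence.taxa
        if recommender.raster is not None:
            taxa |= recommender.raster.taxa
        total_taxa = len(taxa)
    per_query: list[PerQuery] = []
    for n, rec in enumerate(test_records):
        try:
            q = Query(p=rec.location, date=rec.date, r_km=template.r_km, strategy=template.strategy, sources=template.sources)
            result = recommender.recommend(q)
        except OutOfRegionError:
            logger.warning("test record %d outside study region; counted as a miss", n)
            per_query.append(PerQuery(n, None, 0))
            continue
        per_query.append(PerQuery(n, result.rank_of(rec.taxon_id), len(result)))
    return EvaluationReport.from_per_query(per_query, total_taxa, ks=ks)


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint, exhaustive fold assignment with sizes differing by ≤ 1."""

    n_folds: int
    seed: int
    assignment: tuple[int, ...]

    @classmethod
    def random(cls, n_records: int, n_folds: int, seed: int) -> "FoldPlan":
        if n_folds < 2 or n_records < n_folds:
            raise ValueError("need at least 2 folds and one record per fold")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_records)
        assignment = np.empty(n_records, dtype=int)
        assignment[perm] = np.arange(n_records) % n_folds
        return cls(n_folds=n_folds, seed=seed, assignment=tuple(int(a) for a in assignment))

    def test_indices(self, fold: int) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a == fold]

    def train_indices(self, fold: int) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a != fold]


def _mean_report(reports: list[EvaluationReport], ks) -> EvaluationReport:
    ms = [r.M for r in reports if r.M is not None]
    return EvaluationReport(
        n=int(np.sum([r.n for r in reports])),
        R=float(np.mean([r.R for r in reports])),
        R_at={int(k): float(np.mean([r.R_at[int(k)] for r in reports])) for k in ks},
        LL=float(np.mean([r.LL for r in reports])),
        LR=float(np.mean([r.LR for r in reports])),
        MRR=float(np.mean([r.MRR for r in reports])),
        M=int(round(np.mean(ms))) if ms else None,
        per_query=[],
        total_taxa=reports[0].total_taxa if reports else 0,
        meta={"aggregated_over": len(reports)},
    )


def cross_validate(
    occurrences: list[PointOccurrence],
    presence: PresenceAbsenceDataset | None,
    plan: FoldPlan,
    template: QueryTemplate,
    grid: GridSpec,
    config: RecommenderConfig | None = None,
    total_taxa: int | None = None,
    ks=DEFAULT_KS,
) -> tuple[list[EvaluationReport], EvaluationReport]:
    """K-fold cross-validation on point records: per fold, rebuild the raster
    from the training share and query with the held-out records.

    Held-out records without a usable event date are skipped (and counted in
    the fold's meta) when the strategy requires a date.
    """
    if len(plan.assignment) != len(occurrences):
        raise ValueError("fold plan length does not match the record count")
    needs_date = template.strategy in ("S5", "S2+S5")
    reports: list[EvaluationReport] = []
    for fold in range(plan.n_folds):
        test_idx = plan.test_indices(fold)
        if not test_idx:
            raise ValueError(f"fold {fold} holds no test records")
        train = [occurrences[i] for i in plan.train_indices(fold)]
        raster = build_raster(train, grid)
        rec = Recommender(grid, presence=presence, raster=raster, config=config)
        tests = []
        skipped_undated = 0
        for i in test_idx:
            o = occurrences[i]
            if needs_date and not o.date_plausible:
                skipped_undated += 1
                continue
            tests.append(TestRecord(location=o.location, date=o.event_date, taxon_id=o.taxon_id))
        if not tests:
            raise ValueError(f"fold {fold} holds no usable test records")
        report = evaluate(tests, template, rec, total_taxa=total_taxa, ks=ks)
        report.meta.update({"fold": fold, "seed": plan.seed, "skipped_undated": skipped_undated})
        reports.append(report)
    return reports, _mean_report(reports, ks)


def resolution_sweep(
    occurrences: list[PointOccurrence],
    presence: PresenceAbsenceDataset | None,
    test_records: list[TestRecord],
    resolutions: list[tuple[float, float]],
    template: QueryTemplate,
    region_grid: GridSpec,
    config: RecommenderConfig | None = None,
    total_taxa: int | None = None,
    ks=DEFAULT_KS,
) -> pd.DataFrame:
    """Evaluate once per computational-grid resolution (lon, lat arc-seconds);
    one table row per resolution with the metric columns."""
    rows = []
    for lon_step, lat_step in resolutions:
        grid = GridSpec.from_bbox(
            region_grid.origin.lon,
            region_grid.origin.lat,
            region_grid.lon_max,
            region_grid.lat_max,
            lon_step_arcsec=lon_step,
            lat_step_arcsec=lat_step,
        )
        raster = build_raster(occurrences, grid)
        rec = Recommender(grid, presence=presence, raster=raster, config=config)
        rep = evaluate(test_records, template, rec, total_taxa=total_taxa, ks=ks)
        row = {
            "lon_step_arcsec": lon_step,
            "lat_step_arcsec": lat_step,
            "R": rep.R,
            "LL": rep.LL,
            "LR": rep.LR,
            "MRR": rep.MRR,
            "M": rep.M,
        }
        for k in ks:
            row[f"R_{int(k)}"] = rep.R_at[int(k)]
        rows.append(row)
    return pd.DataFrame(rows)
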