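# Methods

## Problem setting

`florarec` estimates, for a query location *p* (WGS84 lon/lat), date *d* and
sampling radius *r* (km), a ranked candidate set of plant taxa likely to be
encountered there. Two data sources feed the estimate: binary per-tile
presence-absence data from systematic floristic mapping, and individually
collected, dated point occurrence records. The two differ in everything that
matters — spatial resolution, sampling design, abundance information,
temporal information — which is precisely why they are complementary and why
the package treats them as two separately scored sources merged at the end.

## Geometry

All distances are great-circle (haversine) on a sphere of radius 6371 km. The
scoring formulas only compare distances up to a few tens of km, where the
difference between spherical and ellipsoidal geodesics (< 0.5%) is far below
the granularity of the survey tiles, so no projection is introduced. Areas of
lon/lat quadrangles are exact on the sphere:
A = R² · Δλ · (sin φ_north − sin φ_south). A 10′×6′ survey tile spans
≈118 km² at 55°N and ≈140 km² at 47.3°N; the default 30″×18″ computational
cell — 1/100 of a quarter tile — is ≈0.33 km² at 50°N.

The computational grid is anchored at the south-west corner of the study
region (default 5–16°E, 47–56°N) with half-open cells
[west, east) × [south, north): a point on a shared edge belongs to the cell
east/north of it. Neighborhoods are closed balls (a center at exactly
distance *r* is included); *r* = 0 is exact-unit retrieval — the containing
tile or cell, not a degenerate ball around the unit center.

## Ingestion and taxonomic harmonisation

Names in all inputs are resolved against a local taxa table carrying accepted
names, synonyms and parent links. Sub-specific entries (subspecies, variety,
form) are subsumed under their species-level parent before any counting, so
both sources and the test set share one taxon vocabulary. Unresolvable names
are skipped and counted, never fatal; every reader reports a per-reason skip
table, and kept + skipped always equals the input row count.

Presence-absence rows flagged questionable or false are dropped. Where a
full-resolution tile and any of its quarter tiles record the same taxon, the
full-tile record is dropped in favour of the newer, finer quarter
information (membership is geometric: a quarter center inside the full
tile's bounds).

Point records are dropped when coordinates are missing, unparseable or
outside the study region, or when the stated coordinate uncertainty exceeds
10 km — beyond that the record carries no signal at any radius the method
studies. Records without an uncertainty get the 500 m default typical of the
aggregated archives this format emulates. Event dates equal to known
data-entry sentinels (1970-01-01), before 1700, or in the future are kept
spatially but flagged implausible, so they contribute occurrence mass but no
phenology mass. The survey-period field of presence data is parsed and
retained but not used in scoring.

## Rasterization

Each point record is a circle centered on its coordinates with radius equal
to its uncertainty; encounter expectation is maximal at the center and
decays linearly to zero at the edge. The kernel is sampled at cell centers
(exact in the fine-grid limit, and consistent with the center-based tile
logic) and renormalised so that every record contributes exactly unit mass;
`counts` therefore remains interpretable as "number of observations". A
record whose circle covers no cell center assigns its whole mass to the
containing cell. One unit of mass per record, rather than uncertainty-
proportional mass, is a deliberate choice: the sources give no reason to let
a vaguer record count for more.

Dated records also spread their unit mass over at most two adjacent monthly
bins. Mid-month is day ⌈(days_in_month+1)/2⌉; the observation's own month
receives 1 − |day − mid|/days_in_month and the remainder goes to the
calendar-adjacent month on the side of the offset, wrapping December–January.

Consequences used as test invariants: total raster mass equals the number of
records; month mass equals the number of date-plausible records;
rasterization is additive over record batches and translation-consistent
away from grid borders.

## Scoring strategies

Support for taxon *t* is P^r_{t,p}: occupied unit centers within *r* with
positive counts. Strategies S1 (mean counts), S2 (mean counts/(1 + d̂)),
S3 (1 − min d/norm), S4 (1 − mean d/norm) and S5 (phenology) are implemented
as stated in the README. Conventions the bare formulas leave open, and how
this package resolves them:

* **S2 distance normalisation** — d̂ = d/r, so the weight 1/(1 + d̂) spans
  [1/2, 1] inside the radius regardless of the radius chosen.
* **S3/S4 normaliser** — the maximum support distance over *all* taxa within
  the radius (global). A per-taxon maximum would score every
  single-occurrence taxon exactly 0 and defeat the intent of ranking by
  proximity; the per-taxon reading remains available via
  `RecommenderConfig(s34_normalizer="per_taxon")`. When all support sits at
  the query point (norm 0) the score defaults to 1.
* **S5 month distance** — circular (Δ = min(|m−m₀|, 12−|m−m₀|)), because
  phenology wraps at the year boundary; the plain linear difference is
  selectable with `s5_circular=False`. The kernel is the standard normal
  density, so unit monthly mass in the query month scores 1/√(2π) ≈ 0.399.
  S5 uses only date-plausible mass: taxa without dated support in the radius
  are not candidates under S5, which is why recall under S5 can differ
  slightly from S1 on the same data.
* **Radius 0** — S1 and S5 evaluate the exact containing unit; S2–S4 (and
  S2+S5) compare distances across multiple units and therefore require
  r > 0, raising otherwise.

## Combining score maps

Both the two data sources and the S2+S5 strategy combination are merged the
same way: each map is scaled by its own maximum onto [0, 1] (scores are
non-negative, so this is min-max normalisation with the floor pinned at
zero), then summed with weights (default 0.5/0.5). Pinning the floor at zero
rather than at the per-map minimum keeps two properties that matter here: a
single-map combination reproduces that map's ranking exactly including its
lowest-scoring taxon, and any taxon with positive evidence in at least one
source stays in the candidate set — the combination can only add candidates,
which is the entire point of merging complementary sources. Since the atlas
source has no dates, the S5 component always comes from the point source
alone; S5 with `sources="grid"` is an error.

Ties are broken by ascending taxon id — an arbitrary but deterministic rule
that makes runs reproducible and testable. Ties are common and meaningful on
the binary atlas source, where S1–S4 collapse to few distinct values at
small radii.

## Evaluation

Average recall R (and truncated R_k), average list length LL, list reduction
LR = (|T|/N) Σ 1/|T_n|, mean reciprocal rank MRR (misses contribute 0), and
median rank M — the smallest rank s such that at least half of the
*retrieved* correct taxa rank ≤ s; misses are excluded from M because it is
defined on the intersection with retrieved lists. Queries with empty
candidate lists are excluded from LR (its term is undefined at |T_n| = 0)
with a logged warning, but still count as misses in R and MRR. Default
report cutoffs are k = 20 (a user-friendly shortlist) and k = 514 (the
median number of taxa per survey tile in the German atlas data this format
mirrors); both configurable. MRR ≤ R always, and R_k is non-decreasing in k
with R_|T| = R — both enforced as test invariants.

Cross-validation rebuilds the point raster per fold from the training share
and queries with the held-out records; fold assignment is a seeded uniform
permutation with fold sizes differing by at most one. Held-out records
without a plausible date are skipped (and counted in the fold report) when
the strategy requires a date, mirroring the fact that phenology scoring
operates on dated records alone. The resolution sweep re-rasterizes and
re-evaluates at each requested computational-grid resolution.

## Synthetic landscapes

The generator emulates the *structure* of the real inputs, not their
geography. Each taxon occupies a circular range disc (log-uniform radius
5–25 km inside a ~150×130 km region); its presence tiles are exactly the
tiles intersecting the disc; point records fall uniformly inside the disc
with per-taxon expected abundance log-uniform over 1–50 (every point-source
taxon is guaranteed at least one record, so source coverage is exact by
construction). Phenology is a wrapped, discretised von-Mises-like monthly
distribution with per-taxon peak and concentration (default 0.5–4). 14% of
records lack a plausible date (half missing, half the 1970-01-01 sentinel)
and 65% lack an explicit uncertainty, matching the rough shares documented
for aggregated occurrence archives; explicit uncertainties are lognormal
around 300 m clipped to [20 m, 5 km]. `source_overlap` controls the fraction
of taxa present in both sources; the remainder alternates between
atlas-only and points-only taxa, emulating e.g. garden plants absent from
wildlife mapping. Test records are drawn inside discs at the taxon's
phenology, with optional label corruption.

What the generator deliberately does **not** reproduce: realistic range
shapes, spatial clustering of recording effort (the real archives
concentrate half their records in under 1% of occupied cells *at specific
places*; here imbalance is only per-taxon), land-cover structure, and
taxonomic ambiguity beyond simple synonym/subspecies links. Passing tests on
this generator therefore demonstrate the correctness of the aggregation,
scoring and evaluation machinery and the *qualitative* orderings (combined
sources beat single sources; spatio-temporal scoring beats plain frequency
in MRR) — not the quantitative recall levels achievable on real atlas and
archive data.

## Problem sizes and numerical choices

Tests and the acceptance script run on landscapes of 15–25 taxa and 150–400
records over the ~150×130 km region, with 30–60 test queries per landscape —
small enough to keep the full suite around a minute while leaving every code
path (both sources, all strategies, all filters) exercised. Oracle
cross-checks use 8–14-cell grids and ≤ 50 records so the reference scorer
can afford full scans over every cell. Score comparisons in tests use
absolute tolerances of 1e-9 (pure float pipelines) and metric identities are
exact. All randomness flows through `numpy.random.default_rng` with explicit
seeds; the test-record stream is seeded independently of the landscape
stream so test sets can be regenerated without replaying the landscape.

## Known limitations

* Scores are relative rankings, not calibrated encounter probabilities.
* The uniform grid index does a windowed scan per query; no spatial index
  beyond the grid itself is built, which is adequate at atlas scale but not
  tuned for continental point densities.
* The atlas source is queried at native tile resolution rather than being
  resampled onto the computational grid; the two-source combination
  therefore mixes support at different granularities, which the per-source
  normalisation absorbs but does not remove.
* No land-cover, elevation or habitat covariates; no fuzzy name matching
  beyond the explicit synonym table.
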