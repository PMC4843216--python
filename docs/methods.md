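# Methods

## Gridding

Point records are projected with a cylindrical equal-area projection at
standard parallel 30° (Behrmann): on a sphere of authalic radius
R = 6371.007 km, x = R·λ·cos 30°, y = R·sin φ / cos 30°.  The authalic
radius is used because the construction's whole point is area fidelity; no
datum is imposed beyond the sphere.  Cells are squares of side 48.24 km
(≈ half a degree at the standard parallel) anchored with a cell corner at
the projected origin; binning is half-open, [k·s, (k+1)·s), so boundary
points are assigned deterministically.  Cells are identified by their
integer (column, row) pair; no global cell id is imposed.  Because the
projection is equal-area and cells are defined in the projected plane,
every cell has planar area exactly s² and planar area is ground area, so
convex-hull areas computed in the plane need no correction.

Grid registration (where cell edges fall) is a free choice: any analysis
quantity that counts cells depends on it, so cell counts from two different
registrations are not comparable and the package keeps one fixed convention.

## Record filtering

A record enters the analysis if its dating interval is at most ±10 years
wide (total width ≤ 20 yr) or if it carries a confident pre/post flag
relative to the cutoff year (default 1980, end of record span default
2008).  An included record is *pre* if its interval ends before the cutoff
and *post* if it starts at or after it ("after 1 Jan 1980" is implemented
as year ≥ 1980, since the data are year-resolution); an interval straddling
the cutoff is placed by its confident flag or excluded from all analyses —
it cannot be put on either side.  The year assigned to a record for the
time-series model is the interval midpoint, floored; dates finer than a
year are truncated to the year, the model's time bin.  Records that are
confidently pre/post but carry no year inform period-level classification
and metrics but not the per-year likelihood, which has no bin to put them
in.

## The persistence model

Sightings of a focal species in its cell are Poisson with yearly rate
r·E_t.  Survey effort E_t is proxied by the number of records of any
species in the cell in year t (`effort_mode="all_species"`); the
`other_species` mode excludes the focal species' own records to avoid
circularity, at the price that the rate becomes unidentifiable in cells
where only the focal species was ever recorded (the posterior then stays at
the prior).

Choices that define the model, each the simplest structure consistent with
its requirements:

* **Plug-in detection rate.**  r̂ = Σn_t / ΣE_t over years up to and
  including the last sighting, when the species was certainly present.
  This is the exact MLE of the truncated series; it is plugged into the
  extinction-time posterior rather than estimated jointly.
* **Absorbing extinction at year granularity.**  The species is present up
  to some unobserved first-absent year τ and absent thereafter; τ ranges
  over the years after the last sighting, plus "still extant at T".
* **Prior.**  P(extant) = 0.5; the remaining 0.5 spread uniformly over the
  finite τ values.  This makes the posterior equal the prior exactly when
  no effort follows the last sighting — a cell nobody revisited yields no
  update — and the tie rule (p = 0.5 ⇒ extant) then retains such species,
  which is the behaviour wanted of assumption II in unsurveyed cells.
* **Threshold.**  The binary call is p ≥ 0.5.

The closed form evaluates exp(−r̂·cumulative effort); a brute-force
enumeration oracle (explicit product of Poisson zero-probabilities per
candidate τ) is part of the package and must agree to 10⁻¹⁰ — it is the
reference implementation for tests, not a fast path.

Numerical notes: effort is allowed to be zero anywhere (e⁰ terms handle it
naturally); a sighting in the final year forces p = 1; the posterior is
non-increasing in any post-last-sighting effort increment.

## Richness and extent of occurrence

Extant calls per (species, cell) under the four assumptions are defined
only for pairs with at least one record.  Richness is the per-cell count of
extant species (zero-richness cells reported).  EOO is the area of the
convex hull of the *centroids* of a species' extant cells, computed in the
equal-area plane; centroids rather than raw points because the extinction
calls are cell-level, and a point-level hull would mix resolutions.  Hulls
with fewer than three non-collinear centroids have area 0; the percentage
relative to assumption I is defined as 100 when both areas are 0 (nested
sets guarantee area ≤ area_I, so 0/0 only arises for ranges too small to
span a hull under any assumption).  No alpha hulls or range buffering —
strict convex hulls only.

## Association models

Cell-level: within each realm, a Bernoulli GLM (logit) of data-absence over
recorded cells, with land cover as two dummies against a forest reference,
the protected-area flag, and mean human influence index.  Never-recorded
cells are representable but excluded from all models.  Cells whose centroid
has no covariates (coastal centroids over sea) are dropped and counted.

Country-level: a grouped binomial GLM of (data-absent cells / surveyed
cells) per country — "surveyed" counting every cell with a record of any
period — against log GDP per capita, peace-index rank and
English-official-language.  All 2³ predictor subsets (including the null)
are ranked by AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with n = number of
countries.  Models within 2 AICc units of the best are competitive, except
that a model nested with the best, differing by exactly one parameter and
with |ΔlogL| < 0.5 (configurable; operationalising "essentially the same
likelihood") is demoted — its extra parameter bought nothing.  Collinearity
is screened by pairwise Pearson |r| > 0.7 (the conventional cut; the
requirement is the check, not the number).

Fitting is IRLS (statsmodels GLM/Binomial) with tolerance 10⁻⁸ and at most
100 iterations.  Degenerate responses (no successes or no failures) and
runaway coefficients (|β| > 15 on the logit scale) are flagged as
non-converged separation rather than reported as estimates.

## Synthetic data generator

The generator emulates the statistical structure of a large, opportunistic,
multi-species sighting database, with ground truth retained:

* landscape: per-cell human influence index ~ Uniform(0, 50), land cover
  (forest/grassland–shrubland/anthrome at 0.40/0.30/0.30), protected-area
  flag (fraction 0.25), a west/east realm split, and ten longitudinal
  country strips with country-level GDP, peace-rank and language
  covariates;
* occupancy: each of 15 species occupies each cell independently
  (p = 0.35);
* extinction: occupied pairs go locally extinct at the cutoff year with
  probability logit⁻¹(Xβ) of the cell covariates (default β: intercept −1,
  standardised HII +1, PA −1, grassland +0.7, anthrome +0.7).  Extinctions
  are concentrated at the cutoff year by default, mirroring the pre/post
  framing; a uniform spread over the post period is available.  One
  occupied species per cell is always spared, so an assemblage never
  collapses entirely — data-absence in the reference scenario is therefore
  attributable to effort collapse, not total extinction, which is what
  makes exact recovery checks possible;
* effort: latent effort is Poisson(2) records per cell-year; each cell's
  post-cutoff effort is forced to zero with probability logit⁻¹(a + Xβ₀),
  β₀ sharing the direction of the extinction drivers (HII +2, PA −2,
  grassland +2, anthrome +2, peace rank +1) and the intercept a calibrated
  by root-finding so the expected forced-zero fraction is 0.30.  Making
  effort collapse covariate-driven reproduces the central confounding of
  opportunistic data — the same anthropogenic factors drive both
  extinction and surveying — and makes the data-absence GLM a correctly
  specified logistic model, so coefficient-direction recovery is a fair
  test;
* sightings: Poisson(r·E) per extant species-cell-year with r = 1; never
  after a true extinction, never in a zero-effort cell-year.

Presets: `high-effort` (the defaults above; the reference recovery
scenario), `sparse-indo-malaya` (post-cutoff effort outside protected areas
cut to a tenth, forced-zero fraction 0.4), `no-extinction-null` (extinction
intercept −30; every data-absence is pure survey failure).

What the generator does *not* emulate: real species' range shapes and
spatial autocorrelation, the heavy-tailed record-density distribution of
real databases, dating uncertainty (every simulated record is exactly
year-dated), taxonomic error, and spatial error in localities.  Passing
recovery tests therefore shows the inference chain is correct under its own
assumptions, not that those assumptions hold for any particular real
database.

## Problem sizes and runtime choices

The reference scenario is a 20×20 grid, 15 species and 60 years
(1949–2008), giving roughly 2×10⁵ records — enough for every per-cell
statistic to be well resolved while a full pipeline pass stays around ten
seconds.  Seed-replication checks use 50 independent generator seeds for
coefficient-direction recovery and 200 replicates for the grouped-GLM ±3 SE
coverage check.  All randomness flows through `numpy.random.default_rng`
from explicit integer seeds; repeated runs at a fixed seed are
byte-identical, including CSV output.

## Known limitations

* The detection rate is per species × cell with no pooling across cells; in
  sparse cells r̂ rests on very few sightings.
* The persistence posterior conditions on the plug-in r̂ rather than
  integrating over its uncertainty; a joint or hierarchical treatment would
  widen the posterior for short histories.
* Effort proxied by record counts is itself an outcome of the sighting
  process; the `other_species` mode mitigates but does not remove the
  circularity.
* The spatial GLMs ignore spatial autocorrelation; standard errors in
  clustered landscapes will be optimistic.
* EOO uses strict convex hulls, which can overstate ranges with disjunct
  distributions.
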