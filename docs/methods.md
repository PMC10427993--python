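# Methods

This note documents the models, the numerical choices, and what the
synthetic worlds do and do not emulate.

## Checklist integration

Two checklist dialects are read onto one record type. The world-checklist
("wcvp") dialect provides accepted names, ranks, the interspecific-hybrid
marker column and (optionally) an artificial-hybrid flag and a per-region
occurrence status; the naturalized-flora ("glonaf") dialect provides name
status, naturalization status (`naturalized` vs `alien` vs `native`) and a
hybrid flag. Filters implement the analysis rules:

* hybrids = accepted natural interspecific hybrids (artificial hybrids and
  unaccepted names removed);
* neophytes = accepted, naturalized, non-hybrid taxa — aliens (unclear
  establishment) are removed, infraspecific neophytes retained since their
  naturalizations equally present hybridization opportunities, and
  hybrid-flagged neophytes removed so hybrids are never regressed on
  hybrids;
* natives (the ratio denominator) = accepted species-rank taxa recorded as
  native. The source analysis does not pin down its native denominator
  precisely; this choice is explicit and the tally function takes the
  native collection as an argument, so callers can substitute another
  definition.

Name matching is deterministic: trim, collapse internal whitespace, strip
the hybrid sign "×", case-sensitive thereafter (live taxonomy
harmonization against name services is deliberately out of scope). Region
codes that are purely numeric — a known mis-coding of botanical-country
identifiers — are dropped and counted, as are empty codes; every reader
reports `retained + dropped = input rows`. Tallies count distinct
normalized names per unit because source tables repeat a name across its
region rows. Regions with neither hybrid nor neophyte records are dropped
(absence of both more plausibly reflects a data-mobilization gap), and
genus ratios may exceed 1 and are never clamped.

## Effort covariates

GDP per capita is recorded per political country and year: the series is
averaged over years (gaps skipped), copied to every botanical country
inside a political country, and averaged without weights where several
political countries share one botanical country. Missing GDP stays missing
(NaN), never zero-filled.

Taxonomist effort is a describer count with a spillage correction: an
author is credited to a region when at least one taxon they described
occurs there, with credit 1 / mean(range sizes of that author's described
taxa occurring in the region), range size being the count of occupied
regions. The mean is taken over the author's taxa *in the focal region*,
not globally — the alternative global reading would under-credit authors
of regional endemics who also described one widespread species; both
readings are supported through the optional `ranges` argument. Shrinking
ranges can only raise scores (each author's credit lies in (0, 1]), which
the suite checks as a monotonicity property.

## Congener encounters

A naturalization event is one (neophyte species, botanical country) pair;
it offers a hybridization opportunity when a native congener is present in
the invaded country (genus identity is the sole crossability criterion —
no phylogenetic-distance modelling). Natives-only presence is used, not
"any earlier-listed species", as the conservative reading. The projection
multiplies the species-level encounter fraction by a hybridization-rate
range (default 9–25% of plant species) and rounds half-away-from-zero to
whole events; this rounding convention reproduces both published bounds of
the projection exactly.

## Diversification rates

Net diversification per genus uses the stem-age method-of-moments
estimator `r = ln(SR·(1−e) + e)/age` — natural log, which the published
840 species/Myr worked example forces; log10 appears only in the
downstream transformation of rates before modelling. `e` defaults to 0.9
with 0.5 as the sensitivity setting. Monotypic genera have `r = 0` exactly
and are excluded from log10 modelling by default (toggleable). The
"extreme rate" flag has no published cutoff, only a count; the default
threshold is therefore the 99.9th percentile of the computed rates, and an
explicit threshold can be supplied. The rate table is always complete;
exclusions are applied only at the inference stage.

## Phylogenetic signal

The Brownian covariance of two tips is their shared root-to-MRCA path
length, assembled in one pass over internal nodes (no quadratic MRCA
scan). K is computed as `[MSE0/MSE] / E[MSE0/MSE]` with the
phylogenetic (GLS) mean, `n−1` divisors, and
`E[MSE0/MSE] = (tr V − n/Σ(V⁻¹)) / (n−1)`; the linear algebra runs through
a Cholesky factorization with a relative pivot tolerance of 1e-10 for
singularity. Traits are raw per-genus counts (tips without tallied taxa
score 0; tallied genera missing from the tree are dropped with a report);
no log-transform is applied before K, since the published values state no
transformation. An optional randomization p-value shuffles tip labels. The
calibration property — mean K within [0.85, 1.15] over ≥200 Brownian
simulations — uses an edge-walk Brownian simulator that shares no code
with the covariance construction.

## Human footprint

Hectad means average all raster cells whose *center* lies inside the
hectad rectangle, half-open on the max edges so no cell is double-counted;
at ~1 km cells in 10 km hectads the difference from area-weighted overlap
is confined to boundary cells. Hectad geometry comes from a rectangle
table in the raster's planar coordinate system (CRS tags are compared, but
no reprojection engine is included — fixtures are generated in the target
CRS). Hectads without coverage, taxa with no joinable hectads, and
triplets missing a type are all omitted *with reports*. The occupancy rule
keeps hybrids occupying strictly more than 10 hectads.

## Bayesian inference

All three model families share a Gaussian likelihood and weakly
informative priors: Normal(0, 2.5·sd(y)/sd(x)) on slopes,
Normal(mean(y), 2.5·sd(y)) on intercepts and cell means, half-Student-t(3,
sd(y)) on every scale (the source analysis states no priors; these mirror
the defaults of the modelling framework it used). Scales use the
inverse-gamma auxiliary representation of the half-t, making every full
conditional conjugate:

* the fixed-effects regression samples (β | σ²) and (σ² | β) by Gibbs;
* the group-means model uses cell means, and contrasts back-transform
  `10^Δ` into rate ratios;
* the hierarchical footprint model (`f = θ_type + α_triplet + b_{type,triplet} + ε`)
  draws **all location parameters jointly** from their multivariate-normal
  full conditional given the scales — coordinate-wise updates mix very
  poorly here because the type means, triplet intercepts and cell effects
  are strongly cross-correlated. The reported type means are the
  population-level θ; contrasts are computed from the same draws, so
  antisymmetry is exact.

Zeros under a log10 transform are dropped with a report by default (the
genus regression is restricted to genera with both hybrids and neophytes,
making counts ≥ 1); a `+1` offset policy is available. Negative values
under log10 are a hard data error. Convergence is enforced post hoc:
split-R̂ < 1.01 and bulk ESS ≥ 400 per parameter (via arviz), surfaced as
exit code 4 by the CLI when strict. The random-slope scale `tau_b` is the
slowest-mixing parameter (a standard funnel); draws are cheap (~0.1 ms), so
the default configuration simply runs enough iterations (4 chains ×
1500–2500 draws) rather than adding reparametrization machinery. For fixed
seed and sampler settings results are bit-stable. The exact
Normal-inverse-gamma/Student-t posterior under a flat prior is exposed as
`ols_t_intervals` and serves as the independent analytic cross-check in the
test suite (the sampled intervals match it and track its frequentist
coverage replicate-for-replicate).

## Synthetic worlds

The generator plants every stage's ground truth and writes it to
`ground_truth.json`:

* **Country world** — per-region neophyte counts, GDP, integer taxonomist
  effort and area are drawn lognormally; hybrid counts follow the
  Gaussian-on-log10 regression with slope 0.26 (covariate slopes 0.10 /
  0.15 / 0.10, residual sd 0.15) and are materialised as checklist rows,
  along with planted filter violators (artificial hybrids, unaccepted
  names, aliens, hybrid neophytes, numeric region codes) in known numbers.
  Latent counts are realised by randomized rounding (unbiased given the
  latent), and regressions are generated from *realized* predictors so the
  planted slope is the regression truth without errors-in-variables
  attenuation. Neophytes come from a shared species pool so one species
  naturalizes in many regions and event- and species-level congener
  fractions differ, as in real data.
* **Genus world** — a separate checklist pair for the ratio regression
  (slope 0.64, residual sd 0.2) over ~600 genera. Planting both the
  country-level and genus-level truths in a single file pair would couple
  the two regressions, so the stages read separate file sets.
* **Diversification world** — a pure-birth tree over 800 genera (terminal
  edges scaled to a ~25 Myr median stem age); each genus gets a group
  (multipliers 1 / 1.6 / 2.5 / 2.91 on a base rate of 0.05 species/Myr,
  lognormal noise sd 0.12 on log10) and a richness found by inverting the
  method-of-moments estimator, so the fitted group contrasts recover the
  multipliers. Monotypic genera are confined to the no-hybrid groups.
  Hybrid/neophyte counts are assigned independently of tree position, so
  the planted truth for phylogenetic signal is "none" and K must sit far
  below 1.
* **Footprint world** — a 200 × 200 cell raster (west–east HFI gradient,
  ~1% missing cells), 400 hectads, and 30 triplets whose per-(taxon, type)
  occupied hectads are matched to target HFI draws at mean 22.6 plus type
  offsets (native 0, neophyte +2.0, hybrid +5.9), with triplet-level
  intercept sd 1.5, type-by-triplet sd 0.8 and observation sd 4.0. Two
  hybrids are planted at exactly 10 hectads to exercise the exclusion
  boundary. Occupancy is scaled down (hybrid/neophyte/native ≈ 34/80/120
  hectads, versus thousands for real native ranges) to keep the default
  pipeline run in seconds.

What the worlds do **not** emulate: real richness distributions beyond
heavy-tailed shapes, taxonomic synonymy and name-matching noise, spatial
autocorrelation of occupancy beyond the raster gradient, observation
effort gradients in occupancy data, and non-Gaussian residuals. Passing
recovery tests therefore demonstrates that the estimators and samplers
recover the parameters of their own generating processes at realistic
scales — not that the empirical coefficients of the original databases are
reproduced, which is impossible without those databases.

## Default sizes and runtime

Defaults are 200 regions, 800 genera, 600 checklist genera and 30 triplets;
a full simulate-plus-pipeline run completes in well under a minute on one
CPU, and the entire test suite (including 100-replicate coverage checks and
200-replicate Brownian calibration) in under a minute.

## Known limitations

* The hectad zonal statistic is exact only for axis-aligned rectangular
  hectads; arbitrary polygons would need a point-in-polygon test.
* The extreme-rate cutoff is a percentile convention, not a biological
  constant.
* The effort model splits no credit among describing teams (each listed
  author gets full credit); authority-string parsing expects pre-tokenized
  author columns.
* The congener criterion ignores ploidy and crossability barriers within
  genera, as in the source analysis.
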