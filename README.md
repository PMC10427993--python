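# neohybrid

Macroecology of plant naturalization and hybridization: do botanical
countries and genera with more naturalized alien plants (**neophytes**) also
hold more interspecific **hybrids**, do lineages containing both diversify
faster, and do hybrids of neophyte × native parentage live in more
human-dominated landscapes than their parents?

The package is a tested, reusable reimplementation of that analysis
pipeline for researchers in invasion macroecology and plant evolution. It
integrates world-checklist-style and naturalized-flora-style species
tables, builds taxonomic-effort covariates, estimates congener-encounter
probabilities at naturalization events, contrasts stem-age diversification
rates across hybrid/neophyte groups, computes phylogenetic signal, and
compares human-footprint distributions for hybrid–native–neophyte triplets
— with a synthetic-data generator that plants known ground truth for every
stage, so the whole pipeline is testable without downloading any database.

## The models at the core

* **Spatial / phylogenetic overlap.** Gaussian regressions on the log10
  scale, `h_i ~ Normal(μ_i, σ)` with
  `μ_i = α + β_n n_i + β_e e_i + β_t t_i + β_a a_i`, where `h_i` is the
  hybrid count (or hybrid-to-native ratio) of botanical country *i* and
  `n_i, e_i, t_i, a_i` are its neophyte count, GDP per capita,
  range-weighted taxonomist count and area. Per genus the model reduces to
  `μ_i = α + β_n n_i` on counts or on ratios per accepted species. A slope
  `b` converts to a percent change via `100·(1.2^b − 1)` for a 20% predictor
  increase.
* **Diversification.** Stem-age method-of-moments net diversification rate
  `r = ln(SR·(1−e) + e)/age` per genus (`SR` species richness, `age` stem
  age in Myr, `e` relative extinction fraction, 0.9 by default and 0.5 as a
  sensitivity setting). Genera are grouped 1–4 by (hybrids present?,
  neophytes present?) and `log10 r` is modelled as `μ_i = α + β_group_i`;
  pairwise group contrasts back-transform (`10^Δ`) to rate ratios.
* **Phylogenetic signal.** Blomberg's K of per-genus hybrid and neophyte
  counts on a genus-level phylogeny: the observed ratio of ordinary to
  Brownian-weighted trait variance over its Brownian-motion expectation
  (K = 1 under Brownian evolution, K → 0 for no signal).
* **Human footprint.** Mean 0–50 human-footprint-index (HFI) per hectad
  (10 × 10 km grid cell), joined to taxon occupancy;
  `f_i ~ Normal(μ_i, σ)` with a varying intercept per triplet and a varying
  type slope per triplet, `μ_i = α_triplet_i + β_type_i,triplet_i`. Only
  hybrids occupying more than 10 hectads enter.
* **Congener encounters.** The fraction of naturalization events (neophyte
  × botanical country) with a native congener present, and the projection
  `n_neophytes × encounter_fraction × hybridization_rate` for a 9–25%
  hybridization-rate range.

All posteriors come from conjugate Gibbs samplers (weakly informative
priors; half-Student-t(3) scales) with split-R̂ and bulk-ESS convergence
checks; 95% equal-tailed credible intervals define "statistical clarity".

## Worked example

Generate a synthetic world (200 botanical countries, 800 genera, 30
hybrid–native–neophyte triplets, seeded) and run the full pipeline:

```bash
neohybrid simulate --outdir demo
neohybrid run --config demo/pipeline_config.yaml
```

The run logs one line per stage and writes `demo/out/report.json`:

```
[spatial] 200 regions; slope 0.240
[genus] 400 genera with both; ratio slope 0.645
[congeners] event fraction 0.586, projection 98-272
[diversification] ratio both/neither 3.05
[signal] K hybrids 0.024, K neophytes 0.037
[footprint] 28 triplets; mean HFI hybrid=28.4, native=22.5, neophyte=24.4
```

Reading these numbers: the posterior mean country-level slope of log10
hybrids on log10 neophytes is 0.240 (95% CI [0.174, 0.306], containing the
generator's planted 0.26) — a 20% increase in neophytes predicts about a
4.5% increase in hybrids. Across the 400 genera containing both, the
hybrid-ratio-on-neophyte-ratio slope is 0.645 (planted 0.64). 58.6% of
naturalization events offer a native congener, projecting 98–272
hybridization events at literature hybridization rates. Genera with both
hybrids and neophytes diversify 3.05× faster than genera with neither (95%
CI [2.88, 3.22], planted 2.91). Hybrid and neophyte counts were planted
with no phylogenetic structure, and K ≈ 0.02–0.04 correctly sits near the
no-signal regime. Hybrids occupy hectads averaging HFI 28.4 versus 22.5
(native parents) and 24.4 (neophyte parents), recovering the planted type
means 28.5 / 22.6 / 24.6; two hybrids planted at exactly 10 hectads are
excluded by the occupancy rule (28 of 30 triplets analysed).

Every stage is also available as a subcommand (`neohybrid spatial`,
`genus`, `congeners`, `diversification`, `signal`, `footprint`) over the
same YAML config, and as plain library functions (`neohybrid.mom_rate`,
`neohybrid.blomberg_k`, `neohybrid.fit_varying_slopes`, ...).

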