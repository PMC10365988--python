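# Methods

## Model and procedure

The quantity of interest is the expected daily environmental footprint of a
diet group, on seven indicators: CO₂ (kg), CH₄ (g), N₂O (g), agricultural
land use (m²), freshwater use (m³), eutrophication potential (g PO₄e) and
terrestrial-vertebrate biodiversity impact (extinction units ×10⁻¹² species),
all per standardized diet-day, plus aggregated CO₂e under multiple
equivalence metrics.

A participant's footprint is linear in intakes:

    F_p(d) = Σ_i  x_{p,i} · d_i

where `x_{p,i}` is the participant's intake (g/day, as consumed) of FFQ item
`i` and `d_i` is the item's per-gram indicator vector. The analysis
propagates two separate sources of uncertainty:

* **Food-level sourcing/production variation** (primary analysis). Each LCA
  category holds many records, one per production system/region. Stage 1
  draws, for iteration `t`, one per-gram vector `d_i(t)` for every item
  simultaneously; stage 2 evaluates every participant under the same draw
  matrix. Reported absolute values are medians and 2.5th/97.5th percentiles
  over iterations of the age–gender standardized group mean. Between-group
  ratios are computed within each iteration and then summarized — common
  random numbers make these far more precise than the absolute intervals,
  and they are deliberately *not* derivable from the absolute tables.
* **Sampling variation across participants** (secondary analysis). Fixing
  each category at its database median, the participant-level footprint is
  regressed on diet group, age band and gender (OLS, categorical dummies);
  marginal means are the average counterfactual prediction over the whole
  cohort's covariate distribution (g-computation), with delta-method CIs
  from the coefficient covariance.

The two analyses disagree by design. Food-level distributions are
right-skewed and zero-bounded, so draws above the median are on average
further from it than draws below; the median of a sum of such draws exceeds
the sum of medians. The package carries this as an explicit diagnostic:
`median_of_sum_oracle` (exhaustive enumeration; two standard dice → 7 = 2 ×
3.5, two doubling dice → 35 ≫ 2 × 12) and `skew_gap` (median of Monte Carlo
diet sums minus the median-fixed sum; zero on a point-mass database,
positive under skew).

### Gas disaggregation and CO₂e metrics

LCA records carry stage-level CO₂e. Gas masses are recovered by inverting
the characterization assumed to have produced them: enteric-fermentation
CO₂e → CH₄ (÷27 kg CO₂e per kg, ×1000 to grams), fertilizer CO₂e → N₂O
(÷273), remainder → CO₂. Re-aggregation with the same factors reproduces the
stage total exactly (a tested round-trip identity). Reported CO₂e applies
the metric registry (AR6: GWP100 27/273, GTP100 11/297, GWP20 86/268) to the
recovered gram masses per iteration. Since the true characterization inside
any given LCA source is usually unstated, the inversion factors are a
documented assumption, configurable on `LCADatabase`.

### Linkage and composition estimation

FFQ items resolve either directly to one LCA category or through retail
products (unweighted mean over matched products, then ÷1000 and × a
sold-to-consumed conversion factor, default 1.0, supplied as input data).
Product compositions obey two labelling constraints: percentages sum to
100% and are non-increasing in label order. Declared percentages are fixed
points; the residual is spread as equally as the ordering permits — each
maximal run of undeclared ingredients takes a common level clipped to
[next anchor, previous anchor], with the level solving the monotone mass
balance (bisection, 100 halvings; this is the exact limit of equal splitting
followed by pooling adjacent violators, and the minimum-norm feasible
allocation). Infeasible declarations (order violations, totals over 100%,
anchors the residual cannot satisfy) raise a diagnosed error. Keyword
matching of items to products is curated input, not an algorithm, so the
link table is part of the data contract.

### Cohort rules

Classification: vegans answer No to all four screening questions (meat,
fish, eggs, dairy); vegetarians No to meat and fish; fish-eaters No to meat
only; meat-eaters split at <50 / [50, 100) / ≥100 g meat per day (boundaries
inclusive on the heavier side, tested exactly). Exclusions, applied in a
fixed order so counts are reproducible (malformed, age, completion,
classification, energy): age outside [20, 80) years, FFQ completion < 0.8,
unclassifiable answers, and daily energy outside [3.3, 16.7] MJ for men or
[2.1, 14.7] MJ for women (1 kcal = 0.004184 MJ). Energy standardization
multiplies all intakes by 2000/energy; it is idempotent and, by linearity,
commutes with footprint computation. A sensitivity switch
(`energy_standardize=False`) reproduces the unstandardized design. Direct
standardization uses age-band × gender strata (10-year bands by default;
the band width is not dictated by the design and is exposed as
configuration) weighted by the whole retained cohort's stratum shares;
strata where a group is empty are dropped from that group's mean with
weights renormalized and a logged warning.

## Random numbers

One root seed governs a run. Every FFQ item owns a counter-keyed substream
(`SeedSequence(seed, spawn_key=(crc32(item_id),))`) from which its full
iteration block is drawn in a fixed traversal of the item's product
structure. Consequences: results are independent of item evaluation order
(reordering the link table leaves each item's draws unchanged, tested),
byte-reproducible given the seed, and every participant shares the draw
matrix — the common-random-number contract that makes proportionally scaled
diets produce exactly constant iteration-wise ratios (tested at zero
tolerance). Draws default to whole-record resampling (`draw_mode="record"`),
preserving within-food cross-indicator coherence; `"marginal"` samples each
indicator independently for sensitivity use. Percentiles use numpy's linear
interpolation between order statistics; with 1,000 iterations the method
choice is visible around the third decimal, so it is fixed and documented
rather than configurable.

## Synthetic data: what it emulates and what it does not

The generators stand in for restricted inputs and define the package's
study conditions:

* **LCA database** — log-normal per-indicator laws, `median · exp(σZ)`,
  chosen as the simplest right-skewed zero-bounded family; stage splits fix
  each category's enteric/fertilizer/other CO₂e shares. Default: 11
  categories, 25 records each, 20% flagged organic, σ between 0.5 (staple
  crops) and 1.0 (beef). Category medians are realistic per-kg magnitudes
  ordered plant < animal on every indicator (chosen once, at design time,
  with an analytic margin check on the implied standardized group means).
* **Cohort** — six diet groups, default 500 participants each; per-group
  age, gender share, energy and nine food-group intake profiles follow the
  published descriptive table of the cohort this emulates (fruit/veg
  portions converted at 80 g/portion). Intakes are gamma-distributed with
  the published mean/sd; meat grams are drawn within each meat group's
  classification band; should-be-nil animal intakes get Bernoulli(0.05)
  contamination with mean 4 g — reproducing the small nonzero animal-food
  means self-assigned plant-based groups show. Ages are truncated to
  [20, 80).
* **Products** — ground-truth compositions are sorted Dirichlet draws
  (sum 100%, non-increasing); masking keeps each percentage with a given
  probability, giving the composition estimator a known-truth validation
  bed. With everything masked, median product-footprint recovery error on
  the default database is reported by the test suite as a data-dependent
  benchmark, not a guarantee.

Not emulated: real joint correlations between foods within a person,
seasonal or secular intake trends, sales-weighted product popularity,
organic-specific footprint differences (organic records share the
conventional law and differ only by flag), and any attempt to match the
real cohort's absolute published footprints — synthetic results support
ordering and mechanism checks, not numeric comparison with the published
tables.

## Problem sizes and numerical choices

Defaults: 1,000 Monte Carlo iterations (2.5/97.5 percentiles), 500
participants per group, 25 records per category. The test suite's
parameter-recovery check compares the pipeline's 1,000-iteration group
medians against an independently coded 120,000-draw simulation oracle,
within four combined bootstrap standard errors (400 bootstrap resamples of
the iteration values, inflated for the oracle's own Monte Carlo error); the
skew checks use 50 items at σ = 1 and 10,000–20,000 iterations. Group
iteration values are accumulated from per-(group, stratum) mean intake
profiles — one matrix product with the draw tensor — so memory stays flat in
cohort size for the default mean statistic; `group_statistic="median"`
requires the participant × iteration cube and is intended for smaller
cohorts. Tolerances: composition sum to 100 within 1e-6, link shares and
stage splits to 1 within 1e-9, stratum weights to 1 within 1e-12.

## Known limitations

* Gas recovery inherits the assumed characterization factors; footprints
  under alternative metrics are exact *given* the recovered gram masses, not
  given the unknown true ones.
* The organic pathway falls back to conventional records (with a warning)
  when a category has no organic LCAs.
* Iteration-wise ratios require a strictly positive reference group in
  every iteration (guaranteed with positive intakes and draws; guarded
  regardless).
* Population scaling (`scale_to_population`) is unit-converting arithmetic
  over supplied prevalences; it makes no claim about national
  representativeness of the cohort.
* The secondary regression is OLS with delta-method CIs; count-like or
  heteroscedastic outcomes may warrant a different family, which the design
  leaves open.
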