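# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions adopted where the design was open.

## Data model

The unit of analysis is an ASV-by-sample matrix of non-negative integer
read counts (`CountTable`), assumed already denoised (e.g. DADA2 output),
with per-sample metadata carrying site, land-use class
(`agri_ditch | agri_stream | mixed | forest`), an ISO-8601 sampling date,
and numeric environmental covariates. Read-level processing, taxonomy
assignment and functional prediction are upstream of this package.

Filter-fraction tables (the same water sample sequenced from two filter
pore sizes) are merged by per-sample, per-ASV addition over the union of
ASV sets; merging is strict about matching sample sets by default because
an unmatched fraction usually signals a bookkeeping error, with a lenient
zero-fill mode for intentionally unbalanced designs.

## Rarefaction

Each retained sample is an exact multivariate-hypergeometric draw of
`depth` reads from the sample's observed reads — subsampling without
replacement, so no count can exceed its input and retained columns sum to
the depth exactly. Samples below depth are dropped rather than kept at
native depth; a fixed-depth basis is what makes Bray-Curtis numerators
comparable across samples. The draw is seeded and bit-reproducible; a
`--replicates` CLI option writes several independent draws for users who
prefer averaging over rarefactions, without prescribing either practice.

## Core selection

Occupancy (fraction of group samples with count > 0) and mean per-sample
relative abundance are each converted to descending ranks (average ranks on
ties); the composite score is their weighted mean with default weight 0.5.
The symmetric weight treats prevalence and abundance as equally informative
— the classical abundance-occupancy framing — and is exposed as
`occupancy_weight` for users who want a prevalence-leaning variant. Final
ranks are made unique by breaking score ties with higher mean abundance,
then lexicographic ASV id, so rankings are deterministic across runs.

The explained-beta curve uses the additive per-taxon decomposition of
Bray-Curtis dissimilarity pooled over all unordered sample pairs in the
analysis group:

    explained(k) = Σ_pairs Σ_{i in top-k} |x_i − y_i|
                 / Σ_pairs Σ_{i in all}   |x_i − y_i|

with a shared full-community denominator. This is the only reading under
which a stepwise "additional 0.5%" rule is coherent: the curve is
non-decreasing by construction and reaches exactly 1 when all taxa are
included. (Dissimilarity share and similarity share are complementary; the
dissimilarity decomposition is used because its per-taxon gains are
additive.) Per-taxon pooled numerators are computed with the sorted-row
identity `Σ_{j<k}|a_j − a_k| = Σ_m (2m − n + 1) a_(m)`, which is
O(n log n) per taxon.

Selection takes the **largest** k whose marginal gain exceeds the threshold
(default 0.005), with explained(0) = 0; a late high-variance taxon
therefore pulls everything ranked above it into the core. If no step
qualifies the core is empty and a warning is logged. All pairs in the
group enter one pool with no temporal blocking, matching a multi-year
pooled selection.

## CRT detection

The coefficient of bimodality is

    b = (g1² + 1) / (g2 + 3(n−1)² / ((n−2)(n−3)))

with bias-corrected (SAS-convention) sample skewness g1 and excess kurtosis
g2. Useful anchors: any two-point distribution has population b = 1; a
normal distribution gives ≈ 0.33 at large n; b is invariant to affine
transforms of the series. n ≥ 4 and a non-constant series are required —
constancy is tested as `max == min` because the standard deviation of a
numerically constant float series can be ~1e-16.

An ASV is flagged CRT when (i) it is not in the supplied core set (core and
CRT are treated as disjoint subcommunities with additive contributions),
(ii) its maximum per-sample relative abundance in the group reaches the
abundance threshold (default 0.1% — the maximum is the natural screen for
sporadically abundant taxa), and (iii) b ≥ 0.90. Degenerate series are
never errors at table level: they are reported non-CRT with a reason code
(`in_core_set`, `below_abundance_screen`, `constant_series`,
`too_few_observations`). Observations are individual samples (site × date)
within the group. An optional `min_rare_fraction` switch additionally
requires the taxon to sit below the abundance threshold in at least that
fraction of samples — off by default, since the maximum screen plus
bimodality already encodes "rare most of the time" for realistic series.

## Contribution series and stability

At each date, all unordered pairs of distinct sites (or blocks) sampled on
that date are pooled: `contribution_pct = 100 · Σ_pairs partial-numerator /
Σ_pairs full-numerator`. Sum-of-numerators aggregation (not mean of
per-pair ratios) preserves exact additivity — per-taxon shares sum to 100%
at every date — and avoids instability when one pair's dissimilarity is
near zero. Dates with fewer than two sites, or zero total dissimilarity,
are skipped with a log entry. Hydrologically connected sites can be
declared as blocks; their count vectors are averaged before pairing so a
block contributes one community profile.

Stability of a subcommunity within one site (or block) and year is
`mean_t(total_t) / sd_t(total_t)` over the within-year sampling dates, with
the sample (n − 1) standard deviation; it equals 1/CV, asserted as a
cross-check between the two functions. At least three dates are required;
missing dates simply shorten the series (no gap interpolation). Stability
is computed per year (years as repeated measures downstream), and grouped
medians/IQRs per land-use class are emitted; cross-class inference (mixed
models) is out of scope.

## Driver correlations

Spearman rho with tie-corrected ranks and two-sided p-values, one test per
covariate, Benjamini-Hochberg adjusted across the covariate family (the
correction is configurable in spirit: the BH step-up is a ~10-line exact
implementation, cross-checked against statsmodels in the tests).
Significance stars (0.05/0.01/0.001/0.0001) are assigned from the adjusted
values. Constant covariates are reported NA with a reason instead of
erroring, so one degenerate probe does not kill a screen.

## Synthetic community generator

The generator emulates the study design the package targets: 8 sites
(4 agricultural drainage ditches, 2 mixed-use, 1 agricultural stream,
1 forested reference), 14 bi-weekly dates from mid-April per season over
2 years, 13,430 reads per sample. Latent per-sample proportions are built
per taxon class, renormalized, and counts drawn multinomially at fixed
depth, so tables are "already rarefied"; `variable_depth=True` draws
Poisson totals around 1.5× depth to exercise the rarefier.

* **Core** (50): iid lognormal relative abundance per taxon-sample, median
  1% (log-sd 0.7) — abundant enough that occupancy is ~1 at depth 13,430
  and each taxon's marginal explained-beta gain sits well above the 0.5%
  stopping threshold. An optional block of site-restricted core taxa is
  planted in one land-use class only.
* **CRT** (100): a two-state process — baseline proportion 1e-5 (mostly
  below one read) and spike proportion 0.5%, a 500× separation. Spike
  dates are drawn per taxon at rate 0.1/date, site-synchronized by default
  (events hit all sites), with only mild per-site amplitude jitter
  (lognormal sd 0.1): the spike state must remain a single latent mode,
  because any substantial amplitude spread blurs the bloom mode and the
  series stops being two-state bimodal. Spike timing can be coupled to the
  discharge covariate: coupling 0 is uniform, coupling 1 confines spikes to
  the covariate's top-decile dates, intermediate values interpolate the
  date weights.
* **Background** (2,000): occupancy drawn uniform(0.01, 0.3), present-cell
  proportions lognormal with median 3e-6, calibrated so the large majority
  of background taxa end with fewer than 10 total reads — a scaled-down
  stand-in for the very large low-count tail of real surveys.

Covariates are seasonal series (temperature sine, spring-freshet discharge
with regional event factors shared across sites, rainfall, nitrate and
suspended solids partly tracking discharge) in conventional units; ASV ids
are neutral and shuffled so labels carry no class information.

**What passing tests do and do not show.** The generator concentrates reads
in the planted structure: core+CRT hold ~95% of each sample, versus a
modest share in real communities whose tail spans >100k taxa. Two
consequences matter. First, recovery rates on synthetic data (core
recall/precision ≈ 1, CRT recall ≈ 0.85 — bounded by taxa that never
spike, ~5% at these rates — background false positives ≈ 0) demonstrate
correctness of the selectors under their own assumptions, not expected
performance on field data. Second, under multinomial closure the combined
core+CRT aggregate is nearly the fixed depth, so its stability is
artificially high; the spikes-inflate-variance mechanism is therefore
asserted as core-only ≫ CRT-only stability, the comparison that survives
closure. Compositional site differences beyond lognormal noise, taxonomic
structure, and mechanistic hydrology are not emulated.

## Numerical conventions and degenerate inputs

* Ties in ranking: average criterion ranks; unique final ranks via
  (score, −abundance, id).
* All-zero samples are flagged, never divided; all-zero sample pairs raise
  an undefined-dissimilarity error; a group whose pairs are all identical
  raises a degenerate-community error.
* Zero-sd stability series are flagged degenerate with infinite stability
  rather than raising, since they occur legitimately in tiny fixtures.
* Every stochastic step (rarefaction, simulation, pipeline) takes an
  explicit integer seed; the pipeline is a pure function of
  (inputs, config, seeds) and its artifacts are byte-reproducible, with
  version/seed/threshold header comments on every TSV.
* Default problem sizes in tests and the acceptance script (10 simulations
  at the full 8-site × 28-date × 13,430-read design, 2,150 taxa) keep a
  complete run in a few seconds on one CPU while preserving the study's
  sampling geometry.

## Known limitations

* The composite-rank weighting (0.5) and the qualification-based stopping
  rule are one concrete reading of abundance-occupancy core selection;
  published variants weight occupancy more heavily or stop at the first
  sub-threshold gain. Both choices are parameters or trivially changed.
* Contribution is computed across sites per date; the per-site-across-dates
  transpose is not implemented.
* The bimodality coefficient cannot distinguish a genuinely bimodal series
  from a single extreme outlier at small n; the optional rarity-fraction
  switch mitigates but does not remove this.
* No inference across land-use classes (mixed models, ordination,
  classifier importance) — those are standard external tools consuming
  this package's outputs.
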