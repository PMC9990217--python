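# aquacore

Core-microbiome and conditionally-rare-taxa (CRT) analysis of temporal ASV
count tables from aquatic 16S rRNA surveys.

Agricultural drainage ditches and small streams carry bacterial communities
that respond quickly to hydrological and nutrient disturbances. Two small
subcommunities summarize most of that dynamic: a **core** of taxa that are
consistently present and abundant over time, and **conditionally rare taxa**
that sit near the detection limit most of the time but sporadically bloom
after events. `aquacore` identifies both from a rarefied ASV-by-sample count
table plus sample metadata, quantifies their share of whole-community
compositional heterogeneity over time, and measures their temporal
stability — the workflow a water-microbiome group needs when turning a
multi-year amplicon survey into indicator subcommunities.

## Methods in brief

* **Rarefaction** — each sample is subsampled without replacement
  (multivariate hypergeometric) to a fixed depth; samples below depth are
  dropped.
* **Core selection** — ASVs are ranked by the mean of their occupancy rank
  and mean-relative-abundance rank. Walking down the ranking, the cumulative
  share of whole-community Bray-Curtis dissimilarity explained by the top-k
  taxa is tracked via the additive decomposition
  `explained(k) = Σ_pairs Σ_{i≤k} |x_i − y_i| / Σ_pairs Σ_all |x_i − y_i|`,
  and selection stops when the marginal gain falls to 0.5% or below.
* **CRT detection** — for each non-core ASV whose relative abundance reaches
  0.1% in at least one sample, the coefficient of bimodality
  `b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))` is computed from
  bias-corrected sample skewness `g1` and excess kurtosis `g2`; taxa with
  `b ≥ 0.90` are flagged CRT.
* **Contribution series** — at each sampling date, the percent of the pooled
  across-site Bray-Curtis numerator attributable to a subcommunity.
* **Stability** — per site and year, mean of the subcommunity's summed
  abundance across dates divided by its sample standard deviation (the
  reciprocal coefficient of variation).
* **Drivers** — Spearman rank correlations of subcommunity abundance against
  environmental covariates, Benjamini-Hochberg adjusted.

A synthetic-community generator plants known core / CRT / background
structure (multi-site, bi-weekly multi-year design at fixed depth) so the
whole pipeline is testable end to end without sequencing data.

## Worked example

```python
from aquacore import (SimulationConfig, simulate_community, core_analysis,
                      detect_crt, contribution_series, community_stability)

sim = simulate_community(SimulationConfig(seed=42))
core = core_analysis(sim.table)                 # 0.5% marginal-gain rule
crt = detect_crt(sim.table, core.core_set)      # b >= 0.90, max >= 0.1%
crt_ids = set(crt.index[crt["is_crt"]])
series = contribution_series(sim.table, sim.metadata, core.core_set | crt_ids)
stab = community_stability(sim.table, sim.metadata, core.core_set)
```

printed summary:

```text
ASV table: 2150 taxa x 224 samples
core: 50 ASVs explaining 84.9% of beta-diversity
CRT: 88 ASVs
core+CRT share of Bray-Curtis heterogeneity: mean 99.0% (range 98.2-99.3%)
median core stability (mean/sd across dates): 13.39
```

The simulated community plants 50 core and 100 CRT taxa among 2,000
low-count background taxa across 8 sites sampled 28 times. The selector
recovers exactly the planted core (50 ASVs) which alone explains ~85% of
the pooled Bray-Curtis dissimilarity; 88 of the 100 planted CRT pass the
bimodality screen (taxa that happened never to spike cannot be detected).
Because the scaled-down community concentrates reads in the planted
structure, core+CRT carry almost all heterogeneity here — on real tables
with a 100k-taxon tail the share is lower. The stability value means the
core's summed abundance is ~13 standard deviations above zero variability
week to week, i.e. highly constant.

The same stages are available from the shell:

```sh
aquacore simulate --out-dir demo
aquacore core --counts demo/counts.tsv --metadata demo/metadata.tsv --out core.tsv
aquacore crt  --counts demo/counts.tsv --metadata demo/metadata.tsv --core core.tsv --out crt.tsv
aquacore run  --config pipeline.yaml      # full pipeline from YAML
```

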