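"""Synthetic multi-site, multi-year ASV community generator.

Emulates the design of a bi-weekly stream/ditch 16S survey: several sites
of mixed land use sampled April-November over multiple years, sequenced to
a fixed per-sample read depth. Three taxon classes are planted:

* **core** — present at every date (occupancy ~ 1) with lognormal
  relative abundance, optionally restricted to one land-use class;
* **CRT** (conditionally rare taxa) — a two-state process: a rarity
  baseline at most dates, with sporadic spikes to a much higher abundance
  (>= 10x the baseline by construction), by default synchronised across
  sites and optionally coupled to a hydrological covariate;
* **background** — a sparse tail with low occupancy (< 0.3) and very low
  counts, most of which end up with only a handful of reads.

Per-sample latent proportions are renormalised and counts drawn
multinomially at fixed depth, so generated tables are "already rarefied";
``variable_depth=True`` instead draws Poisson-varying totals to exercise
rarefaction itself. The generator is a pure function of its config
(identical seed => identical output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .asv_io import CountTable

COVARIATE_NAMES = ("TEMP_C", "RAIN_MM", "RU_DISM3S", "NITRATE", "SUSSOL")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and taxon-class parameters for the generator.

    Defaults emulate eight sites (four agricultural drainage ditches, two
    mixed-use, one agricultural stream, one forested reference) sampled
    bi-weekly 14 times per season over two years at a depth of 13,430
    reads per sample, with 50 core, 100 CRT and 2,000 background taxa.
    """

    n_sites: int = 8
    n_dates: int = 14          # sampling dates per year (bi-weekly Apr-Nov)
    n_years: int = 2
    n_core: int = 50
    n_crt: int = 100
    n_background: int = 2000
    depth: int = 13_430        # reads per sample after rarefaction
    core_logmean: float = math.log(0.01)   # log relative-abundance scale
    core_logsd: float = 0.7
    crt_baseline: float = 1e-5             # rarity-state proportion
    crt_spike_abundance: float = 0.005     # spike-state proportion (500x base)
    crt_spike_prob: float = 0.1            # per-date spike probability
    crt_spike_site_sd: float = 0.1         # lognormal sd of per-site spike size
    # kept small so the spike state stays a single latent mode: larger
    # spreads blur the bloom mode and the series is no longer two-state
    site_synchronized_spikes: bool = True
    background_logmean: float = math.log(3e-6)
    background_logsd: float = 1.2
    background_max_occupancy: float = 0.3
    covariate_coupling: float = 0.5        # 0 = independent, 1 = top-decile only
    coupled_covariate: str = "RU_DISM3S"   # water discharge drives spike timing
    n_site_specific_core: int = 0          # extra core planted in one class only
    site_specific_class: str = "agri_ditch"
    variable_depth: bool = False           # pre-rarefaction mode
    start_year: int = 2017
    seed: int = 0

    def validate(self) -> None:
        if self.n_core + self.n_crt + self.n_background < 1:
            raise ValueError("at least one taxon must be simulated")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("crt_spike_prob", "covariate_coupling",
                     "background_max_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("crt_baseline", "crt_spike_abundance"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a proportion")
        if min(self.n_sites, self.n_dates, self.n_years) < 1:
            raise ValueError("n_sites, n_dates and n_years must be >= 1")
        if self.coupled_covariate not in COVARIATE_NAMES:
            raise ValueError(f"unknown covariate {self.coupled_covariate!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Everything a downstream test needs: table, metadata, planted truth."""

    table: CountTable
    metadata: pd.DataFrame          # one row per sample, indexed by sample_id
    truth: pd.DataFrame             # asv_id, class, site_restricted
    spike_dates: pd.DataFrame       # CRT asv_id x date boolean spike schedule
    covariates: pd.DataFrame        # (site, date) covariate values


def _land_use_assignment(n_sites: int) -> list[str]:
    # ditch-heavy design mirroring an agricultural watershed survey
    base = ["agri_ditch"] * max(1, n_sites // 2)
    base += ["mixed"] * max(0, n_sites - len(base) - 2)
    if len(base) < n_sites:
        base.append("agri_stream")
    if len(base) < n_sites:
        base.append("forest")
    return base[:n_sites]


def _sampling_dates(cfg: SimulationConfig) -> pd.DatetimeIndex:
    dates = []
    for y in range(cfg.n_years):
        start = pd.Timestamp(year=cfg.start_year + y, month=4, day=15)
        dates.extend(start + pd.Timedelta(days=14) * k for k in range(cfg.n_dates))
    return pd.DatetimeIndex(dates)


def simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Seasonal environmental covariates per (site, date).

    Water temperature follows a within-season sine; rainfall and discharge
    share date-level "event" factors (storms are regional), with nitrate and
    suspended solids partly tracking discharge. Units mirror typical water
    chemistry reporting (degC, mm, m3/s, mg/L).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dates = _sampling_dates(cfg)
    sites = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    n_d = len(dates)
    frac = np.tile(np.linspace(0.0, 1.0, cfg.n_dates), cfg.n_years)

    rain_event = rng.exponential(scale=8.0, size=n_d)            # regional storms
    discharge_event = rng.lognormal(mean=0.0, sigma=0.8, size=n_d)
    rows = []
    for site in sites:
        site_scale = rng.lognormal(0.0, 0.3)
        temp = 14.0 + 9.0 * np.sin(np.pi * frac) + rng.normal(0, 1.5, n_d)
        rain = rain_event * rng.lognormal(0.0, 0.3, n_d)
        discharge = (
            0.4 * (1.0 + 1.5 * np.exp(-4.0 * frac))               # spring freshet
            * discharge_event * site_scale * rng.lognormal(0.0, 0.2, n_d)
        )
        nitrate = np.maximum(
            0.02, 1.2 + 0.8 * np.log(discharge_event) + rng.normal(0, 0.5, n_d)
        )
        sussol = np.maximum(1.0, 60.0 * discharge_event * rng.lognormal(0.0, 0.4, n_d))
        rows.append(pd.DataFrame({
            "site": site, "date": dates, "TEMP_C": temp, "RAIN_MM": rain,
            "RU_DISM3S": discharge, "NITRATE": nitrate, "SUSSOL": sussol,
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["event_score"] = pd.Series(discharge_event, index=dates)
    return out


def _spike_weights(event_score: np.ndarray, coupling: float) -> np.ndarray:
    """Date-selection weights interpolating uniform -> top-decile-only."""
    n = len(event_score)
    n_top = max(1, int(math.ceil(0.1 * n)))
    top = np.zeros(n)
    top[np.argsort(event_score)[::-1][:n_top]] = n / n_top
    w = (1.0 - coupling) + coupling * top
    return w / w.sum()


def simulate_community(cfg: SimulationConfig) -> SimulationResult:
    """Generate a planted-structure count table with metadata and truth.

    Returns a :class:`SimulationResult`; ``truth`` labels every ASV exactly
    once as core, crt or background, and ``spike_dates`` records the planted
    CRT spike schedule for downstream contrast tests.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    covariates = simulate_covariates(cfg, rng)
    event_score = covariates.attrs["event_score"]
    dates = pd.DatetimeIndex(event_score.index)
    sites = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    land_use = dict(zip(sites, _land_use_assignment(cfg.n_sites)))
    n_d, n_s = len(dates), len(sites)
    n_samples = n_d * n_s
    n_core_total = cfg.n_core + cfg.n_site_specific_core
    n_taxa = n_core_total + cfg.n_crt + cfg.n_background

    # samples ordered site-major, date-minor; ids encode site and date
    sample_site = np.repeat(np.arange(n_s), n_d)
    sample_date = np.tile(np.arange(n_d), n_s)
    sample_ids = [
        f"{sites[s]}_{dates[d].strftime('%Y%m%d')}"
        for s, d in zip(sample_site, sample_date)
    ]

    W = np.zeros((n_taxa, n_samples))
    row = 0

    # core: lognormal proportion at every (taxon, sample)
    core_rows = slice(row, row + cfg.n_core)
    W[core_rows] = rng.lognormal(cfg.core_logmean, cfg.core_logsd,
                                 (cfg.n_core, n_samples))
    row += cfg.n_core

    # site-restricted core: core-level abundance only in one land-use class
    ss_rows = slice(row, row + cfg.n_site_specific_core)
    if cfg.n_site_specific_core:
        in_class = np.array(
            [land_use[sites[s]] == cfg.site_specific_class for s in sample_site]
        )
        block = rng.lognormal(cfg.core_logmean, cfg.core_logsd,
                              (cfg.n_site_specific_core, n_samples))
        W[ss_rows] = np.where(in_class[None, :], block, 0.0)
    row += cfg.n_site_specific_core

    # CRT: baseline everywhere, spikes on scheduled dates
    crt_rows = slice(row, row + cfg.n_crt)
    spike = np.zeros((cfg.n_crt, n_d), dtype=bool)
    weights = _spike_weights(event_score.to_numpy(), cfg.covariate_coupling)
    eligible = np.flatnonzero(weights > 0)
    for i in range(cfg.n_crt):
        m = rng.binomial(n_d, cfg.crt_spike_prob)
        m = min(m, len(eligible))
        if m:
            chosen = rng.choice(eligible, size=m, replace=False,
                                p=weights[eligible] / weights[eligible].sum())
            spike[i, chosen] = True
    if cfg.site_synchronized_spikes:
        spike_sample = spike[:, sample_date]
    else:
        # independent per-site schedules drawn at the same rate
        spike_sample = np.zeros((cfg.n_crt, n_samples), dtype=bool)
        for s in range(n_s):
            cols = np.flatnonzero(sample_site == s)
            for i in range(cfg.n_crt):
                m = rng.binomial(n_d, cfg.crt_spike_prob)
                m = min(m, len(eligible))
                if m:
                    chosen = rng.choice(eligible, size=m, replace=False,
                                        p=weights[eligible] / weights[eligible].sum())
                    spike_sample[i, cols[chosen]] = True
    site_jitter = rng.lognormal(0.0, cfg.crt_spike_site_sd, (cfg.n_crt, n_samples))
    W[crt_rows] = np.where(
        spike_sample, cfg.crt_spike_abundance * site_jitter, cfg.crt_baseline
    )
    row += cfg.n_crt

    # background: sparse tail, occupancy < background_max_occupancy
    bg_rows = slice(row, row + cfg.n_background)
    if cfg.n_background:
        occ = rng.uniform(0.01, cfg.background_max_occupancy, cfg.n_background)
        present = rng.random((cfg.n_background, n_samples)) < occ[:, None]
        level = rng.lognormal(cfg.background_logmean, cfg.background_logsd,
                              (cfg.n_background, n_samples))
        W[bg_rows] = np.where(present, level, 0.0)

    P = W / W.sum(axis=0, keepdims=True)

    if cfg.variable_depth:
        depths = rng.poisson(int(round(cfg.depth * 1.5)), n_samples)
    else:
        depths = np.full(n_samples, cfg.depth)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(depths[j], P[:, j])

    # neutral, shuffled ASV ids so labels carry no class information
    perm = rng.permutation(n_taxa)
    asv_ids = np.empty(n_taxa, dtype=object)
    asv_ids[perm] = [f"ASV_{k + 1:06d}" for k in range(n_taxa)]
    classes = (
        ["core"] * n_core_total + ["crt"] * cfg.n_crt
        + ["background"] * cfg.n_background
    )
    restricted = (
        [False] * cfg.n_core + [True] * cfg.n_site_specific_core
        + [False] * (cfg.n_crt + cfg.n_background)
    )
    truth = (
        pd.DataFrame({"asv_id": asv_ids, "class": classes,
                      "site_restricted": restricted})
        .sort_values("asv_id")
        .reset_index(drop=True)
    )

    table = CountTable(pd.DataFrame(counts, index=asv_ids, columns=sample_ids))
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "site": [sites[s] for s in sample_site],
        "land_use_class": [land_use[sites[s]] for s in sample_site],
        "date": [dates[d] for d in sample_date],
        "year": [dates[d].year for d in sample_date],
    })
    metadata = metadata.merge(covariates, on=["site", "date"], how="left")
    metadata = metadata.set_index("sample_id", drop=False)

    crt_ids = asv_ids[crt_rows]
    spike_df = pd.DataFrame(spike, index=crt_ids, columns=dates).sort_index()
    return SimulationResult(table=table, metadata=metadata, truth=truth,
                            spike_dates=spike_df, covariates=covariates)


def config_with(cfg: SimulationConfig, **overrides) -> SimulationConfig:
    """Return a copy of ``cfg`` with fields replaced (convenience)."""
    return replace(cfg, **overrides)
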