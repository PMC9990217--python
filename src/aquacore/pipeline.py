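"""End-to-end orchestration: simulate/ingest -> rarefy -> core -> CRT ->
contribution -> stability -> environmental-driver correlations.

The pipeline is a pure function of (inputs, config, seeds): rerunning with
the same config writes byte-identical artifacts. Every stage's table is
written as TSV with ``#`` header comments recording version, seed and
thresholds, so each stage can be reloaded and rerun on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .asv_io import (
    CountTable,
    rarefy,
    read_count_table,
    read_metadata,
    to_relative_abundance,
    validate_metadata,
    write_count_table,
    write_metadata,
)
from .beta import contribution_series
from .core_selection import DEFAULT_CORE_THRESHOLD, core_analysis
from .crt import (
    DEFAULT_ABUNDANCE_THRESHOLD,
    DEFAULT_B_THRESHOLD,
    detect_crt,
    partition_labels,
)
from .exceptions import AquacoreError, ValidationError
from .stability import community_stability, grouped_summary
from .synthetic import SimulationConfig, simulate_community

logger = logging.getLogger("aquacore")

SIGNIFICANCE_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


# ---------------------------------------------------------------------------
# report arithmetic
# ---------------------------------------------------------------------------

def percent_share(part: int | float, whole: int | float, ndigits: int = 1) -> float:
    """part / whole as a percentage, rounded to ``ndigits`` decimals."""
    if whole == 0:
        raise ValidationError("percent_share: whole is zero")
    return round(100.0 * part / whole, ndigits)


def summarize_partition(n_core: int, n_crt: int, n_total: int) -> dict:
    """Percent of all ASVs held by the core, the CRT, and their union."""
    return {
        "n_core": n_core,
        "n_crt": n_crt,
        "n_total": n_total,
        "core_pct": percent_share(n_core, n_total),
        "crt_pct": percent_share(n_crt, n_total),
        "combined_pct": percent_share(n_core + n_crt, n_total),
    }


# ---------------------------------------------------------------------------
# environmental drivers
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1). NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def _stars(q: float) -> str:
    if np.isnan(q):
        return ""
    for cut, sym in SIGNIFICANCE_STARS:
        if q <= cut:
            return sym
    return ""


def spearman_drivers(
    series: pd.Series,
    covariates: pd.DataFrame,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlation of a response series against each covariate.

    ``series`` and ``covariates`` are aligned on their index (typically
    (site, date) or sample id). Rho uses tie-corrected ranks with a
    two-sided p-value; Benjamini-Hochberg adjustment is applied across the
    covariate family and significance stars (0.05/0.01/0.001/0.0001) are
    assigned from the adjusted values. Constant covariates are reported as
    NA with a reason.
    """
    rows = []
    for name in covariates.columns:
        joined = pd.concat([series, covariates[name]], axis=1, join="inner").dropna()
        n = len(joined)
        if n < min_pairs:
            raise ValidationError(
                f"covariate {name!r}: only {n} paired observations "
                f"(need >= {min_pairs})"
            )
        y = joined.iloc[:, 0].to_numpy(dtype=float)
        x = joined.iloc[:, 1].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"covariate": name, "n": n, "rho": np.nan,
                         "p": np.nan, "reason": "constant_series"})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"covariate": name, "n": n, "rho": float(rho),
                     "p": float(p), "reason": ""})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"])
    out["stars"] = out["q"].map(_stars)
    return out[["covariate", "n", "rho", "p", "q", "stars", "reason"]]


# ---------------------------------------------------------------------------
# pipeline config + runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, grouping and thresholds for a full analysis run."""

    out_dir: str = "aquacore_out"
    counts_path: str | None = None        # mutually exclusive with simulation
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    group_by: str = "land_use_class"
    groups: tuple = ()                    # empty = one all-samples group
    core_threshold: float = DEFAULT_CORE_THRESHOLD
    b_threshold: float = DEFAULT_B_THRESHOLD
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD
    rarefaction_depth: int | None = None  # None = input already rarefied
    seed: int = 0
    covariate_columns: tuple = ()         # empty = autodetect numeric columns

    def validate(self) -> None:
        for name in ("core_threshold", "b_threshold", "abundance_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        has_files = self.counts_path is not None and self.metadata_path is not None
        if has_files == (self.simulation is not None):
            raise ValidationError(
                "provide either counts_path+metadata_path or a simulation config"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("groups", "covariate_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _header(cfg: PipelineConfig, stage: str) -> list[str]:
    return [
        f"aquacore {__version__} stage={stage}",
        f"seed={cfg.seed} core_threshold={cfg.core_threshold} "
        f"b_threshold={cfg.b_threshold} "
        f"abundance_threshold={cfg.abundance_threshold}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
               index: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header(cfg, stage):
            fh.write(f"# {line}\n")
        out = df.copy()
        if "date" in out.columns:
            out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage per group and write all artifacts under ``out_dir``.

    Returns the summary dict (also written as ``summary.tsv``): per group
    the core size, CRT size, their percentages of all analyzed ASVs, the
    mean subcommunity contributions, and per-unit stability of the
    combined core+CRT subcommunity.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulation is not None:
        sim = simulate_community(cfg.simulation)
        table, metadata = sim.table, sim.metadata
        write_count_table(table, out / "counts.tsv", _header(cfg, "counts"))
        write_metadata(metadata, out / "metadata.tsv")
        sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        table = read_count_table(cfg.counts_path)
        metadata = read_metadata(cfg.metadata_path)
    validate_metadata(table, metadata)

    if cfg.rarefaction_depth is not None:
        table = rarefy(table, cfg.rarefaction_depth, cfg.seed)
        metadata = metadata.loc[table.sample_ids]
        write_count_table(table, out / "counts_rarefied.tsv",
                          _header(cfg, "rarefy"))

    if cfg.groups:
        group_samples = {
            g: list(metadata.index[metadata[cfg.group_by] == g])
            for g in cfg.groups
        }
    else:
        group_samples = {"all": list(metadata.index)}

    if cfg.covariate_columns:
        cov_cols = list(cfg.covariate_columns)
    else:
        reserved = {"sample_id", "site", "land_use_class", "year"}
        cov_cols = [
            c for c in metadata.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(metadata[c])
        ]

    summary_rows = []
    for group, samples in group_samples.items():
        if len(samples) < 2:
            raise AquacoreError(f"stage=core group={group}: fewer than 2 samples")
        try:
            core_res = core_analysis(table, samples, cfg.core_threshold)
        except AquacoreError as exc:
            raise AquacoreError(f"stage=core group={group}: {exc}") from exc
        _write_tsv(core_res.ranked, out / f"core_{group}.tsv", cfg, "core")

        crt_res = detect_crt(table, core_res.core_set, samples,
                             cfg.b_threshold, cfg.abundance_threshold)
        _write_tsv(crt_res, out / f"crt_{group}.tsv", cfg, "crt")
        crt_set = frozenset(crt_res.index[crt_res["is_crt"]])

        labels = partition_labels(crt_res, core_res.core_set)
        subcommunities = {
            "core": core_res.core_set,
            "crt": crt_set,
            "core_plus_crt": core_res.core_set | crt_set,
        }
        contrib_frames = []
        for name, sub in subcommunities.items():
            series = contribution_series(table, metadata, sub, samples)
            series.insert(1, "subcommunity", name)
            contrib_frames.append(series)
        contrib = pd.concat(contrib_frames, ignore_index=True)
        _write_tsv(contrib, out / f"contribution_{group}.tsv", cfg,
                   "contribution", index=False)

        stab = community_stability(table, metadata,
                                   subcommunities["core_plus_crt"])
        stab_sub = stab[stab["unit"].isin(
            set(metadata.loc[samples, "site"]))]
        _write_tsv(stab_sub, out / f"stability_{group}.tsv", cfg,
                   "stability", index=False)
        stab_summary = grouped_summary(stab_sub, metadata)
        _write_tsv(stab_summary, out / f"stability_summary_{group}.tsv",
                   cfg, "stability", index=False)

        drivers = None
        if cov_cols:
            rel = to_relative_abundance(table.subset_samples(samples))
            combined = sorted(subcommunities["core_plus_crt"])
            resp = rel.data.loc[combined].sum(axis=0)
            cov = metadata.loc[samples, cov_cols]
            try:
                drivers = spearman_drivers(resp, cov)
                _write_tsv(drivers, out / f"drivers_{group}.tsv", cfg,
                           "drivers", index=False)
            except ValidationError as exc:
                logger.warning("stage=drivers group=%s skipped: %s", group, exc)

        n_analyzed = len(labels)
        shares = summarize_partition(len(core_res.core_set), len(crt_set),
                                     n_analyzed)
        mean_contrib = (
            contrib.groupby("subcommunity")["contribution_pct"].mean()
        )
        summary_rows.append({
            "group": group,
            "n_samples": len(samples),
            "n_asvs_analyzed": n_analyzed,
            **shares,
            "mean_contribution_core_pct": mean_contrib.get("core", np.nan),
            "mean_contribution_crt_pct": mean_contrib.get("crt", np.nan),
            "mean_contribution_combined_pct": mean_contrib.get(
                "core_plus_crt", np.nan),
        })

    summary = pd.DataFrame(summary_rows)
    _write_tsv(summary, out / "summary.tsv", cfg, "summary", index=False)
    return {row["group"]: row for row in summary_rows}
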