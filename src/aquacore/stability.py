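"""Temporal community stability (constancy) and coefficient of variation.

Stability of a subcommunity within one site (or block) and year is the
temporal mean of its summed abundance across sampling dates divided by
the sample (n-1) standard deviation of the same series — the reciprocal
of the coefficient of variation. High values mean the subcommunity's
aggregate abundance barely moves between successive sampling dates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .asv_io import CountTable
from .exceptions import (
    InsufficientTimepointsError,
    UndefinedCVError,
    ValidationError,
)

logger = logging.getLogger("aquacore")

MIN_TIMEPOINTS = 3


def coefficient_of_variation(series) -> float:
    """Sample CV = sd(n-1) / mean; requires >= 2 values and nonzero mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least two values")
    mean = x.mean()
    if mean == 0.0:
        raise UndefinedCVError("CV undefined for zero-mean series")
    return float(x.std(ddof=1) / mean)


def _unit_stability(totals: np.ndarray) -> tuple[float, float, float, bool]:
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    degenerate = sd == 0.0
    stability = np.inf if degenerate else mean / sd
    return mean, sd, stability, degenerate


def community_stability(
    table: CountTable,
    metadata: pd.DataFrame,
    subcommunity,
    site: str | None = None,
    year: int | None = None,
    block_map: dict | None = None,
    min_timepoints: int = MIN_TIMEPOINTS,
) -> pd.DataFrame:
    """Stability of a subcommunity per (site-or-block, year) unit.

    For each unit the subcommunity's counts are summed per sampling date
    (multiple samples on one date — e.g. filter fractions — are summed
    first) and stability = mean / sd(n-1) of the date series. Units with
    fewer than ``min_timepoints`` dates are skipped, unless a single unit
    was requested explicitly, in which case an error is raised. A zero-sd
    series is reported with ``degenerate=True`` and infinite stability.

    Returns a DataFrame with columns ``unit``, ``year``, ``n_timepoints``,
    ``mean_total``, ``sd_total``, ``stability``, ``degenerate``.
    """
    sub = [a for a in table.asv_ids if a in set(subcommunity)]
    meta = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
    if site is not None:
        unit_of = (lambda s: block_map.get(s, s)) if block_map else (lambda s: s)
        meta = meta[meta["site"].map(unit_of) == site]
    if year is not None:
        meta = meta[meta["year"] == year]
    if meta.empty:
        raise ValidationError("no samples match the requested unit/year")
    sub_counts = table.data.loc[sub, meta.index].sum(axis=0)
    work = meta[["site", "year", "date"]].copy()
    work["unit"] = (
        work["site"].map(lambda s: block_map.get(s, s)) if block_map
        else work["site"]
    )
    work["total"] = sub_counts.to_numpy()
    per_date = (
        work.groupby(["unit", "year", "date"], sort=True)["total"].sum()
    )
    rows = []
    explicit = site is not None and year is not None
    for (unit, yr), series in per_date.groupby(level=["unit", "year"]):
        totals = series.to_numpy(dtype=float)
        if totals.size < min_timepoints:
            if explicit:
                raise InsufficientTimepointsError(
                    f"unit {unit} year {yr}: {totals.size} dates "
                    f"< required {min_timepoints}"
                )
            logger.info("community_stability: skipping %s %s (%d dates)",
                        unit, yr, totals.size)
            continue
        mean, sd, stab, degen = _unit_stability(totals)
        rows.append({
            "unit": unit, "year": yr, "n_timepoints": totals.size,
            "mean_total": mean, "sd_total": sd, "stability": stab,
            "degenerate": degen,
        })
    return pd.DataFrame(
        rows,
        columns=["unit", "year", "n_timepoints", "mean_total", "sd_total",
                 "stability", "degenerate"],
    )


def grouped_summary(
    stability_table: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Median and IQR of stability per land-use class (finite values only)."""
    site_class = metadata.drop_duplicates("site").set_index("site")[
        "land_use_class"
    ]
    df = stability_table.copy()
    df["land_use_class"] = df["unit"].map(site_class)
    df = df[np.isfinite(df["stability"])]
    out = (
        df.groupby("land_use_class")["stability"]
        .agg(median="median",
             q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75),
             n="size")
        .reset_index()
    )
    return out
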