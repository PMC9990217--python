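"""Conditionally-rare-taxa (CRT) detection via the coefficient of bimodality.

A conditionally rare taxon sits at or below a rarity threshold most of the
time and sporadically surges to appreciable abundance, which makes its
relative-abundance distribution over samples bimodal (a rarity mode and a
bloom mode). Bimodality is scored with

    b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))),

where g1 is the sample skewness and g2 the sample excess kurtosis, both
with small-sample (SAS-convention) corrections. For any two-point
population b = 1 exactly; a normal population gives b ~ 0.33. An ASV is
flagged CRT when b >= 0.90, its maximum per-sample relative abundance
reaches 0.1%, and it is not already in the core set (core and CRT are
treated as disjoint subcommunities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .asv_io import CountTable
from .exceptions import (
    DegenerateSeriesError,
    InsufficientObservationsError,
    ValidationError,
)

DEFAULT_B_THRESHOLD = 0.90
DEFAULT_ABUNDANCE_THRESHOLD = 0.001  # 0.1% relative abundance

# reason codes for non-CRT verdicts
REASON_OK = "ok"
REASON_CORE = "in_core_set"
REASON_SCREEN = "below_abundance_screen"
REASON_CONSTANT = "constant_series"
REASON_SHORT = "too_few_observations"


def bimodality_coefficient(series) -> float:
    """Sample coefficient of bimodality of a numeric series.

    Uses bias-corrected sample skewness g1 and excess kurtosis g2
    (SAS convention):

        b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))).

    Requires n >= 4 and a non-constant series.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise InsufficientObservationsError(
            f"bimodality coefficient needs n >= 4, got {n}"
        )
    if x.max() == x.min():  # exact: np.std of a constant can be ~1e-16
        raise DegenerateSeriesError("constant series has undefined bimodality")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1**2 + 1.0) / (g2 + corr))


def detect_crt(
    table: CountTable,
    core_set,
    samples=None,
    b_threshold: float = DEFAULT_B_THRESHOLD,
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
    min_rare_fraction: float | None = None,
) -> pd.DataFrame:
    """Score every ASV's relative-abundance series for conditional rarity.

    Per ASV the per-sample relative-abundance series within the group is
    formed; taxa whose maximum never reaches ``abundance_threshold`` are
    screened out before computing b, and core-set members are excluded
    (reason-coded, never errored). ``min_rare_fraction``, when set,
    additionally requires the taxon to sit below ``abundance_threshold``
    in at least that fraction of samples, enforcing that a CRT is actually
    rare most of the time.

    Returns a DataFrame indexed by asv_id with columns ``b``, ``skewness``,
    ``excess_kurtosis``, ``max_relabund``, ``n_obs``, ``is_crt``,
    ``reason``.
    """
    if samples is not None:
        if len(samples) == 0:
            raise ValidationError("empty sample group")
        table = table.subset_samples(samples)
    if table.shape[1] == 0:
        raise ValidationError("empty sample group")
    core = set(core_set)
    X = table.counts.astype(float)
    col_sums = X.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    rel = X / col_sums
    n_obs = rel.shape[1]
    records = []
    for i, asv in enumerate(table.asv_ids):
        series = rel[i]
        max_rel = float(series.max())
        rec = {
            "asv_id": asv,
            "b": np.nan,
            "skewness": np.nan,
            "excess_kurtosis": np.nan,
            "max_relabund": max_rel,
            "n_obs": n_obs,
            "is_crt": False,
            "reason": REASON_OK,
        }
        if asv in core:
            rec["reason"] = REASON_CORE
        elif max_rel < abundance_threshold:
            rec["reason"] = REASON_SCREEN
        elif n_obs < 4:
            rec["reason"] = REASON_SHORT
        elif series.max() == series.min():
            rec["reason"] = REASON_CONSTANT
        else:
            n = n_obs
            g1 = stats.skew(series, bias=False)
            g2 = stats.kurtosis(series, fisher=True, bias=False)
            corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
            b = (g1**2 + 1.0) / (g2 + corr)
            rec.update(b=float(b), skewness=float(g1), excess_kurtosis=float(g2))
            passes = b >= b_threshold
            if passes and min_rare_fraction is not None:
                rare_frac = float((series < abundance_threshold).mean())
                passes = rare_frac >= min_rare_fraction
            rec["is_crt"] = bool(passes)
        records.append(rec)
    return pd.DataFrame(records).set_index("asv_id")


def partition_labels(crt_result: pd.DataFrame, core_set) -> pd.Series:
    """Label every analyzed ASV as exactly one of core / crt / other."""
    core = set(core_set)
    labels = {}
    for asv, row in crt_result.iterrows():
        if asv in core:
            labels[asv] = "core"
        elif row["is_crt"]:
            labels[asv] = "crt"
        else:
            labels[asv] = "other"
    return pd.Series(labels, name="class")
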