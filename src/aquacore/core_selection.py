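"""Abundance-occupancy core-microbiome selection.

ASVs are ranked jointly by occupancy (fraction of samples with a nonzero
count) and mean per-sample relative abundance; the core is then grown down
the ranking while tracking the cumulative share of whole-community
Bray-Curtis dissimilarity the included taxa explain, and selection stops
once the marginal gain from the next taxon drops to the threshold
(default 0.5%) or below.

The explained share uses the additive per-taxon decomposition of the
pooled Bray-Curtis numerator (see :mod:`aquacore.beta`): explained(k) is
the top-k taxa's summed numerators over the all-taxa total, which makes
the curve non-decreasing with explained(n) = 1 and the stepwise gain rule
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .asv_io import CountTable
from .beta import pooled_taxon_numerators
from .exceptions import DegenerateCommunityError, ValidationError

logger = logging.getLogger("aquacore")

DEFAULT_CORE_THRESHOLD = 0.005


def occupancy_abundance_rank(
    table: CountTable,
    samples=None,
    occupancy_weight: float = 0.5,
) -> pd.DataFrame:
    """Composite abundance-occupancy ranking of ASVs within a sample group.

    Each ASV receives a rank by occupancy and a rank by mean relative
    abundance (1 = best, average ranks for ties); the composite score is
    their weighted mean (default weight 0.5: symmetric). Final composite
    ranks 1..n are assigned by ascending score, ties broken by higher mean
    relative abundance then lexicographic ASV id. ASVs with zero total
    count in the group are excluded (occupancy-0 taxa cannot be core).

    Returns a DataFrame indexed by asv_id in composite-rank order with
    columns ``occupancy``, ``mean_relabund``, ``composite_rank``.
    """
    if samples is not None:
        if len(samples) == 0:
            raise ValidationError("empty sample group")
        table = table.subset_samples(samples)
    if table.shape[1] == 0:
        raise ValidationError("empty sample group")
    X = table.counts.astype(float)
    present = X.sum(axis=1) > 0
    X = X[present]
    ids = np.asarray(table.asv_ids, dtype=object)[present]
    col_sums = X.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    rel = X / col_sums
    occupancy = (X > 0).mean(axis=1)
    mean_rel = rel.mean(axis=1)
    r_occ = rankdata(-occupancy, method="average")
    r_ab = rankdata(-mean_rel, method="average")
    score = occupancy_weight * r_occ + (1.0 - occupancy_weight) * r_ab
    order = np.lexsort((ids, -mean_rel, score))
    df = pd.DataFrame(
        {
            "occupancy": occupancy[order],
            "mean_relabund": mean_rel[order],
            "composite_rank": np.arange(1, len(order) + 1),
        },
        index=pd.Index(ids[order], name="asv_id"),
    )
    return df


def explained_bc_curve(
    table: CountTable,
    ranked: pd.DataFrame,
    samples=None,
) -> np.ndarray:
    """Cumulative share of pooled Bray-Curtis dissimilarity explained by the
    top-k ranked ASVs, for k = 1..n.

    explained(k) = sum over all unordered sample pairs of the top-k taxa's
    |x_i - y_i| numerators, divided by the same sum over all taxa. The
    shared full-community denominator makes the curve additive: it is
    non-decreasing and reaches exactly 1 at k = n.
    """
    if samples is not None:
        table = table.subset_samples(samples)
    if table.shape[1] < 2:
        raise ValidationError("explained_bc_curve needs at least two samples")
    X = table.data.loc[ranked.index].to_numpy(dtype=float)
    numerators = pooled_taxon_numerators(X)
    total = numerators.sum()
    if total == 0.0:
        raise DegenerateCommunityError("all sample pairs are identical")
    return np.cumsum(numerators) / total


@dataclass(frozen=True)
class CoreResult:
    """Outcome of core selection: ranking, explained curve and core set."""

    ranked: pd.DataFrame        # asv_id-indexed, with explained + is_core cols
    explained_curve: np.ndarray
    core_set: frozenset
    threshold: float
    k_selected: int


def select_core(
    ranked: pd.DataFrame,
    curve: np.ndarray,
    threshold: float = DEFAULT_CORE_THRESHOLD,
) -> CoreResult:
    """Apply the marginal-gain stopping rule to an explained-beta curve.

    With explained(0) = 0, the selected size is the largest k whose
    stepwise gain explained(k) - explained(k-1) exceeds ``threshold``; the
    core is the top-k ranked ASVs. If no step qualifies the core is empty
    (warned).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValidationError("empty explained curve")
    if len(ranked) != curve.size:
        raise ValidationError("ranking and curve lengths differ")
    gains = np.diff(np.concatenate([[0.0], curve]))
    if np.any(gains < -1e-12):
        raise ValidationError("explained curve is not non-decreasing")
    qualifying = np.flatnonzero(gains > threshold)
    k_sel = int(qualifying.max()) + 1 if qualifying.size else 0
    if k_sel == 0:
        logger.warning("select_core: no marginal gain exceeds %.4g; empty core",
                       threshold)
    out = ranked.copy()
    out["explained"] = curve
    out["is_core"] = out["composite_rank"] <= k_sel
    core = frozenset(out.index[out["is_core"]])
    return CoreResult(ranked=out, explained_curve=curve, core_set=core,
                      threshold=threshold, k_selected=k_sel)


def core_analysis(
    table: CountTable,
    samples=None,
    threshold: float = DEFAULT_CORE_THRESHOLD,
    occupancy_weight: float = 0.5,
) -> CoreResult:
    """Rank, compute the explained curve, and select the core in one call."""
    ranked = occupancy_abundance_rank(table, samples, occupancy_weight)
    curve = explained_bc_curve(table, ranked, samples)
    return select_core(ranked, curve, threshold)
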