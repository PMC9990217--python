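"""Independent brute-force oracles used to validate the implementation.

Everything here is computed from definitional formulas with explicit
loops — no scipy shortcuts, no calls into aquacore — so the oracles stay
independent of the code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- moment statistics (SAS small-sample conventions) -----------------------

def skewness_oracle(x) -> float:
    x = [float(v) for v in x]
    n = len(x)
    m = sum(x) / n
    s = math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))
    return n / ((n - 1) * (n - 2)) * sum(((v - m) / s) ** 3 for v in x)


def excess_kurtosis_oracle(x) -> float:
    x = [float(v) for v in x]
    n = len(x)
    m = sum(x) / n
    s = math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))
    fourth = sum(((v - m) / s) ** 4 for v in x)
    return (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * fourth
        - 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


def bimodality_oracle(x) -> float:
    n = len(x)
    g1 = skewness_oracle(x)
    g2 = excess_kurtosis_oracle(x)
    return (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


# -- abundance-occupancy ranking --------------------------------------------

def _average_ranks_desc(values) -> list[float]:
    """Rank 1 = largest; ties get the average of their positions."""
    ranks = []
    for v in values:
        greater = sum(1 for w in values if w > v)
        equal = sum(1 for w in values if w == v)
        ranks.append(greater + (equal + 1) / 2.0)
    return ranks


def composite_ranking_oracle(counts: np.ndarray, asv_ids, occupancy_weight=0.5):
    """Ordered asv_id list per the composite abundance-occupancy rank."""
    counts = np.asarray(counts, dtype=float)
    keep = [i for i in range(counts.shape[0]) if counts[i].sum() > 0]
    col_sums = counts.sum(axis=0)
    occ, ab, ids = [], [], []
    for i in keep:
        row = counts[i]
        occ.append(sum(1 for v in row if v > 0) / len(row))
        ab.append(sum(row[j] / col_sums[j] for j in range(len(row))
                      if col_sums[j] > 0) / len(row))
        ids.append(asv_ids[i])
    r_occ = _average_ranks_desc(occ)
    r_ab = _average_ranks_desc(ab)
    score = [occupancy_weight * a + (1 - occupancy_weight) * b
             for a, b in zip(r_occ, r_ab)]
    order = sorted(range(len(ids)), key=lambda i: (score[i], -ab[i], ids[i]))
    return [ids[i] for i in order]


# -- Bray-Curtis decomposition ----------------------------------------------

def bray_curtis_oracle(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def explained_curve_oracle(counts: np.ndarray) -> np.ndarray:
    """Cumulative explained share for taxa in the given row order, pooling
    partial numerators over every unordered column pair independently."""
    counts = np.asarray(counts, dtype=float)
    n_taxa, n_samples = counts.shape
    numer = np.zeros(n_taxa)
    for j, k in itertools.combinations(range(n_samples), 2):
        for i in range(n_taxa):
            numer[i] += abs(counts[i, j] - counts[i, k])
    return np.cumsum(numer) / numer.sum()


def contribution_pct_oracle(vectors, subset_idx) -> float:
    """Percent share of the pooled numerator for a taxon subset across all
    unordered pairs of per-site vectors at one date."""
    num_sub = 0.0
    num_full = 0.0
    for x, y in itertools.combinations(vectors, 2):
        for i in range(len(x)):
            d = abs(x[i] - y[i])
            num_full += d
            if i in subset_idx:
                num_sub += d
    return 100.0 * num_sub / num_full


# -- Spearman rho ------------------------------------------------------------

def spearman_oracle(x, y) -> float:
    """Pearson correlation of tie-corrected average ranks, by definition."""
    def ranks(v):
        return _average_ranks_desc([-u for u in v])  # ascending ranks
    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
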