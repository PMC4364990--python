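"""Social-matrix statistics.

Descriptive statistics over dyadic matrices: Shannon-based evenness of
partner use, rowwise Kendall matrix reciprocity (Tau-Kr), rank-distance
categorization, partner-specificity SD within rank-distance classes, and
rowwise Pearson predictability pooled with a Fisher-z mean.  Diagonals
are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankDistanceStructure",
    "shannon_evenness",
    "taukr",
    "rank_distance_categorize",
    "partner_specificity_sd",
    "rowwise_pearson",
    "fisher_z_mean",
    "summarize_run",
]


def _offdiag_rows(x: np.ndarray):
    """Yield (row_i_without_diag, col_i_without_diag) per agent."""
    n = x.shape[0]
    for i in range(n):
        mask = np.arange(n) != i
        yield x[i, mask], x[mask, i]


def shannon_evenness(row: Sequence[float]) -> float:
    """Evenness of one agent's partner distribution, in (0, 1].

    Shannon entropy (natural log, 0*log 0 := 0) of the normalized row,
    exponentiated and divided by the number of possible partners, i.e.
    exp(H)/(N-1).  Returns NaN for an all-zero row (no acts: undefined,
    excluded from group means).
    """
    p = np.asarray(row, dtype=float)
    if np.any(p < 0):
        raise ValueError("partner weights must be >= 0")
    total = p.sum()
    if total <= 0:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(h) / len(p))


def mean_group_evenness(matrix: np.ndarray) -> float:
    """Group mean of per-individual evenness; NaN rows are excluded."""
    vals = [shannon_evenness(row) for row, _ in _offdiag_rows(np.asarray(matrix))]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def taukr(x: np.ndarray, max_skipped_fraction: float = 0.9) -> float:
    """Rowwise Kendall matrix correlation of X with its transpose.

    For each agent i, the tie-corrected Kendall tau-b between what i
    directs to everyone else and what everyone else directs to i; the
    statistic is the unweighted mean over rows where both vectors vary.
    Returns NaN when more than ``max_skipped_fraction`` of rows are
    unusable (sparse matrix guard).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if x.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    taus = []
    skipped = 0
    for given, received in _offdiag_rows(x):
        if np.ptp(given) == 0 or np.ptp(received) == 0:
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = stats.kendalltau(given, received).statistic
        if np.isnan(t):
            skipped += 1
            continue
        taus.append(t)
    if not taus or skipped > max_skipped_fraction * n:
        return float("nan")
    return float(np.mean(taus))


@dataclass(frozen=True)
class RankDistanceStructure:
    """Dyad categorization by dominance difference."""

    doms: tuple[float, ...]
    similar_threshold: float = 0.35

    @property
    def signed_dist(self) -> np.ndarray:
        d = np.asarray(self.doms)
        return d[None, :] - d[:, None]

    @property
    def abs_dist(self) -> np.ndarray:
        return np.abs(self.signed_dist)


def rank_distance_categorize(
    doms: Sequence[float], threshold: float = 0.35
) -> dict[str, object]:
    """Split dyads into similar- vs distant-ranking.

    Similar means absolute dominance difference strictly below the
    threshold.  Returns the unordered pair lists plus unordered and
    directed counts for both categories.
    """
    doms = np.asarray(doms, dtype=float)
    n = len(doms)
    if n < 2:
        raise ValueError("need at least two agents")
    similar, distant = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(doms[i] - doms[j]) < threshold:
                similar.append((i, j))
            else:
                distant.append((i, j))
    return {
        "similar_pairs": similar,
        "distant_pairs": distant,
        "n_similar_unordered": len(similar),
        "n_distant_unordered": len(distant),
        "n_similar_directed": 2 * len(similar),
        "n_distant_directed": 2 * len(distant),
    }


def partner_specificity_sd(
    x: np.ndarray,
    doms: Sequence[float],
    kind: str = "directed",
    decimals: int = 9,
) -> float:
    """Mean within-rank-distance SD of a dyadic measure.

    Directed matrices are grouped by signed rank distance over ordered
    dyads; symmetric ones by absolute rank distance over unordered
    dyads.  Each group with at least two dyads contributes its sample SD
    (ddof=1); groups of one (the extreme rank distances) are excluded.
    Zero exactly when the measure is a pure function of rank distance.
    """
    x = np.asarray(x, dtype=float)
    doms = np.asarray(doms, dtype=float)
    n = len(doms)
    if x.shape != (n, n):
        raise ValueError("matrix and dominance vector disagree on group size")
    groups: dict[float, list[float]] = {}
    if kind == "directed":
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                key = round(float(doms[j] - doms[i]), decimals)
                groups.setdefault(key, []).append(float(x[i, j]))
    elif kind == "symmetric":
        for i in range(n):
            for j in range(i + 1, n):
                key = round(float(abs(doms[j] - doms[i])), decimals)
                groups.setdefault(key, []).append(float(x[i, j]))
    else:
        raise ValueError("kind must be 'directed' or 'symmetric'")
    # spread at or below 1e-12 is float noise (e.g. the rank-distance
    # formula evaluated at different dominance pairs), not specificity
    sds = [
        0.0 if max(v) - min(v) <= 1e-12 else float(np.std(v, ddof=1))
        for v in groups.values()
        if len(v) >= 2
    ]
    return float(np.mean(sds)) if sds else float("nan")


def rowwise_pearson(x: np.ndarray, p: np.ndarray) -> float:
    """Pooled absolute rowwise Pearson correlation between two matrices.

    Per-row r between the off-diagonal entries of X and the predictor P,
    pooled across usable rows with a Fisher-z mean; the absolute value of
    the pooled correlation is returned.  NaN when no row has variance in
    both matrices.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape or x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("need two square matrices of identical shape")
    n = x.shape[0]
    rs = []
    for i in range(n):
        mask = np.arange(n) != i
        a, b = x[i, mask], p[i, mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    if not rs:
        return float("nan")
    return abs(fisher_z_mean(rs))


def fisher_z_mean(rs: Sequence[float]) -> float:
    """Pool correlations via Fisher z: tanh(mean(atanh(r))).

    Inputs at exactly +/-1 are clipped just inside the open interval
    (with a warning) so the transform stays finite.
    """
    r = np.asarray(rs, dtype=float)
    if r.size == 0:
        raise ValueError("no correlations to pool")
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    lim = 1.0 - 1e-12
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation(s) at +/-1 clipped for Fisher-z pooling")
        r = np.clip(r, -lim, lim)
    return float(np.tanh(np.mean(np.arctanh(r))))


def summarize_run(
    rates: dict[str, np.ndarray],
    proximity: np.ndarray,
    like_mean: np.ndarray,
    doms: Sequence[float],
) -> dict[str, dict[str, float]]:
    """Per-behaviour statistics bundle for one run's averaged matrices."""
    doms = np.asarray(doms, dtype=float)
    rankdist = np.abs(doms[:, None] - doms[None, :])
    out: dict[str, dict[str, float]] = {}
    measures: dict[str, tuple[np.ndarray, str]] = {
        b: (m, "directed") for b, m in rates.items()
    }
    measures["proximity"] = (proximity, "symmetric")
    measures["like"] = (like_mean, "directed")
    for name, (mat, kind) in measures.items():
        out[name] = {
            "taukr": taukr(mat),
            "mean_h_star": mean_group_evenness(mat),
            "sd_partner_specificity": partner_specificity_sd(mat, doms, kind=kind),
            "rowwise_pearson_vs_rankdist": rowwise_pearson(mat, rankdist),
            "rowwise_pearson_vs_like": rowwise_pearson(mat, like_mean),
        }
    return out
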