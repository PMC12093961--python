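"""Nonparametric group comparison with a compact letter display.

Per-cell scores (peak intensities, autofluorescence intensity) are compared
across species with a Kruskal-Wallis omnibus test followed by Dunn's
large-sample rank comparisons in the Hollander-Wolfe formulation:

    Z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]

with mid-ranks, tie correction T = sum(t^3 - t) / (12 (N - 1)), and pair
(i, j) declared different when |Z_ij| >= z_{1 - alpha / (k (k-1))} — the
single-step Bonferroni-type adjustment over all k(k-1)/2 two-sided
comparisons.  Decisions are summarized as a compact letter display: groups
sharing a letter are not declared different.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "dunn_holland_wolfe",
    "letter_display",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    names: list[str]
    h_statistic: float
    omnibus_p: float
    z_matrix: np.ndarray
    decisions: np.ndarray
    alpha: float
    letters: dict[str, str]


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in data):
        raise ValueError("every group needs at least one observation")
    return names, data


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value.

    The degenerate all-identical case returns H = 0, p = 1.
    """
    _, data = _as_groups(groups)
    if sum(g.size for g in data) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(data)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*data)
    return float(h), float(p)


def dunn_holland_wolfe(groups, alpha: float = 0.05):
    """Pairwise Dunn z-comparisons on ranks; returns (decisions, z, names).

    decisions[i, j] is True when groups i and j are declared different at
    familywise level alpha (single-step adjustment alpha / (k (k-1)) per
    one-sided tail).
    """
    names, data = _as_groups(groups)
    k = len(data)
    sizes = np.array([g.size for g in data])
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    mean_ranks = np.asarray(mean_ranks)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j] = zij
            z[j, i] = -zij
    crit = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    decisions = np.abs(z) >= crit
    np.fill_diagonal(decisions, False)
    return decisions, z, names


def letter_display(decisions: np.ndarray, names: list[str] | None = None) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups that are *not* declared different share at least one letter;
    groups declared different share none.
    """
    decisions = np.asarray(decisions, dtype=bool)
    k = decisions.shape[0]
    if decisions.shape != (k, k) or not np.array_equal(decisions, decisions.T):
        raise ValueError("decision matrix must be square and symmetric")
    if np.any(np.diag(decisions)):
        raise ValueError("diagonal of the decision matrix must be empty")
    if names is None:
        names = [f"group{i}" for i in range(k)]
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not decisions[i, j]:
                continue
            new_columns: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_columns.append(col - {i})
                    new_columns.append(col - {j})
                else:
                    new_columns.append(col)
            # deduplicate, then absorb columns contained in another
            unique: list[set[int]] = []
            for col in new_columns:
                if col not in unique:
                    unique.append(col)
            columns = [c for c in unique if not any(c < o for o in unique)]
    # order columns by their smallest member for stable, readable letters
    columns.sort(key=lambda c: min(c) if c else k)
    alphabet = string.ascii_lowercase
    letters = {name: "" for name in names}
    for pos, col in enumerate(c for c in columns if c):
        mark = alphabet[pos % 26] * (1 + pos // 26)
        for g in sorted(col):
            letters[names[g]] += mark
    return letters


def compare_groups(groups, alpha: float = 0.05) -> GroupComparison:
    """Omnibus test, pairwise procedure, and letters in one call."""
    names, _ = _as_groups(groups)
    h, p = kruskal_wallis(groups)
    decisions, z, names = dunn_holland_wolfe(groups, alpha=alpha)
    letters = letter_display(decisions, names)
    return GroupComparison(
        names=names, h_statistic=h, omnibus_p=p, z_matrix=z,
        decisions=decisions, alpha=alpha, letters=letters,
    )
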