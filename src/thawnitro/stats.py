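"""Nonparametric group statistics with compact letter displays.

The analysis layer used throughout: Kruskal–Wallis omnibus tests followed
by Dunn's pairwise z-tests on mean ranks (tie-corrected pooled variance),
multiplicity adjustment (Holm by default, Bonferroni or none selectable),
compact letter displays summarizing the pairwise pattern, Wilcoxon
signed-rank tests for paired treatment contrasts, and Spearman rank
correlations.

Dunn's test statistic for groups i, j on the joint ranking of N values:

    z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) · (1/n_i + 1/n_j) )

with tie correction T = Σ(t³ − t) / (12(N − 1)) over tie groups of size t;
two-sided p-values from the standard normal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "kruskal_dunn",
    "dunn_pairwise",
    "compact_letters",
    "paired_test",
    "rank_correlation",
]

_ADJUST_MAP = {"none": None, "holm": "holm", "bonferroni": "bonferroni"}


@dataclass
class ComparisonResult:
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adj, significant
    letters: dict[str, str]
    alpha: float
    adjust: str
    all_tied: bool = False  # every value identical across groups: H undefined


def dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-statistics and raw two-sided p for every group pair."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n_total = values.size
    ranks = sps.rankdata(values)
    # tie correction over tie groups in the pooled sample
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = math.sqrt(var_unit * (1.0 / n[g1] + 1.0 / n[g2]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[g1] - mean_rank[g2]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def kruskal_dunn(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> ComparisonResult:
    """Kruskal–Wallis omnibus test with Dunn's pairwise post hoc comparisons.

    ``adjust`` ∈ {"none", "holm", "bonferroni"} controls the multiplicity
    correction of the pairwise p-values; the compact letter display is
    built from the adjusted significance pattern at ``alpha``.
    """
    if adjust not in _ADJUST_MAP:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST_MAP)}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least one observation")

    all_tied = np.all(values == values[0])
    if all_tied:
        h, p_omni = 0.0, 1.0  # H undefined with all values tied; p = 1 by convention
    else:
        h, p_omni = sps.kruskal(*samples)

    pw = dunn_pairwise(values, groups)
    if adjust == "none":
        pw["p_adj"] = pw["p_raw"]
    else:
        pw["p_adj"] = multipletests(pw["p_raw"].to_numpy(), method=_ADJUST_MAP[adjust])[1]
    pw["significant"] = pw["p_adj"] < alpha

    sig = {(r.group1, r.group2) for r in pw.itertuples() if r.significant}
    letters = compact_letters(
        np.array([[(g1, g2) in sig or (g2, g1) in sig for g2 in labels] for g1 in labels]),
        list(labels),
    )
    return ComparisonResult(
        omnibus_stat=float(h),
        omnibus_p=float(p_omni),
        pairwise=pw,
        letters=letters,
        alpha=alpha,
        adjust=adjust,
        all_tied=bool(all_tied),
    )


def compact_letters(significant: np.ndarray, groups: list) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Guarantees the two display axioms: a significantly different pair
    shares no letter, and a non-significant pair shares at least one.
    Absorption removes redundant letter columns; minimality of the letter
    count is not guaranteed (nor needed for display purposes).
    """
    significant = np.asarray(significant, dtype=bool)
    k = len(groups)
    if significant.shape != (k, k):
        raise ValueError("significance matrix shape must match groups")
    if not np.array_equal(significant, significant.T):
        raise ValueError("significance matrix must be symmetric")

    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not significant[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.append(col - {i})
            columns.append(col - {j})
        # absorb: drop columns contained in another
        columns = [
            c
            for idx, c in enumerate(columns)
            if c and not any(c < d or (c == d and idx2 < idx) for idx2, d in enumerate(columns) if idx2 != idx)
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for i in sorted(col):
            out[groups[i]] += letter
    return out


def paired_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Returns ``(statistic, p, degenerate)`` where the statistic is the sum
    of signed ranks (so swapping x and y flips its sign) and ``degenerate``
    is True when every difference is zero (no test possible; p = 1).
    Zero differences are dropped; the exact null distribution is used for
    n ≤ 25 without ties, the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be matched vectors of length >= 2")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    ranks = sps.rankdata(np.abs(d))
    signed_stat = float(np.sum(np.sign(d) * ranks))
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    return signed_stat, float(res.pvalue), False


def _spearman_exact_p(rho: float, n: int) -> float:
    """Exact two-sided p for Spearman's rho by enumerating rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    # rho for untied ranks: 1 - 6*sum(d^2)/(n(n^2-1))
    d2 = ((perms - base) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; returns (rho, two-sided p).

    The p-value is exact (full permutation enumeration) for n ≤ 9 without
    ties, otherwise the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    if x.size <= 9 and no_ties:
        p = _spearman_exact_p(float(rho), x.size)
    return float(rho), float(p)
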