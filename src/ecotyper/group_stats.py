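"""Permutational and rank-based tests for cluster validation.

PERMANOVA tests whether a grouping explains pairwise community
distances: the pseudo-F compares between- to within-group sums of
squared distances and its null distribution comes from permuting the
group labels (one-factor design, no strata).  Kruskal-Wallis and
post-hoc pairwise rank tests compare trait distributions across
clusters.

Note on naming: the post-hoc comparisons here are Mann-Whitney
rank-sum tests.  A signed-rank test is sometimes named in this role in
the ecological literature, but it applies only to paired observations
and cannot compare independent clusters of unequal size; use
:func:`scipy.stats.wilcoxon` directly for genuinely paired inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix

ADJUST_METHODS = {"none": None, "holm": "holm", "bonferroni": "bonferroni", "BH": "fdr_bh"}


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    """SS_within = sum_g (sum of squared within-group distances) / n_g."""
    group_sums = np.einsum("ik,ij,jk->k", onehot, d2, onehot)
    return float((group_sums / sizes).sum() / 2.0)


def permanova(
    d: DistanceMatrix,
    labels: np.ndarray | list,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with an add-one permutation p-value.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums within-group pair
    terms scaled by group size; pseudo-F = (SS_between / (k-1)) /
    (SS_within / (n-k)).  The p-value is
    (1 + #{permuted F >= observed}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = values[counts < 2]
        raise ValueError(f"groups of size 1 not allowed: {list(small)}")
    n, k = len(labels), len(values)
    d2 = d.matrix**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    codes = np.searchsorted(values, labels)
    onehot = np.eye(k)[codes]
    ss_within = _ss_within(d2, onehot, counts.astype(float))
    ss_between = ss_total - ss_within
    df_between, df_within = k - 1, n - k
    f_obs = (ss_between / df_between) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        sw = _ss_within(d2, onehot[perm], counts.astype(float))
        sb = ss_total - sw
        f_perm = (sb / df_between) / (sw / df_within)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=float(p),
        n_permutations=n_permutations,
        df_between=df_between,
        df_within=df_within,
    )


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    adjust_method: str = "none"
    flagged: bool = False


def kruskal_wallis(values: np.ndarray | list, groups: np.ndarray | list) -> GroupTestResult:
    """Kruskal-Wallis H (tie-corrected), chi-square p with k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if np.ptp(values) == 0:
        return GroupTestResult(statistic=0.0, p_value=1.0, flagged=True)
    h, p = sps.kruskal(*samples)
    return GroupTestResult(statistic=float(h), p_value=float(p))


def pairwise_wilcoxon(
    values: np.ndarray | list,
    groups: np.ndarray | list,
    adjust: str = "holm",
) -> GroupTestResult:
    """All-pairs Mann-Whitney rank-sum tests with p-adjustment.

    The exact null distribution is used when the smaller group has at
    most 8 observations and there are no ties across the pair;
    otherwise the normal approximation with continuity correction.
    """
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(ADJUST_METHODS)}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("every group needs >= 2 values")
    rows = []
    for g1, g2 in combinations(uniq, 2):
        a, b = values[groups == g1], values[groups == g2]
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=True)
        rows.append({"group1": g1, "group2": g2, "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue), "method": method})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adjusted"] = table["p_raw"]
    else:
        table["p_adjusted"] = multipletests(table["p_raw"], method=ADJUST_METHODS[adjust])[1]
    stat = float(table["statistic"].max()) if len(table) else float("nan")
    p_min = float(table["p_adjusted"].min()) if len(table) else 1.0
    return GroupTestResult(statistic=stat, p_value=p_min, pairwise=table, adjust_method=adjust)


def correlation_test(x: np.ndarray | list, y: np.ndarray | list) -> tuple[float, float]:
    """Pearson r with two-sided t-test p (n - 2 df).

    Zero-variance input yields ``(nan, nan)``; callers should treat
    that as "undefined" rather than "not significant".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
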