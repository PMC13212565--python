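"""Group-comparison scaffold used by every figure-style contrast.

The branching logic mirrors common practice for habitat/lineage panels:
a Shapiro-Wilk normality gate on pooled within-group residuals chooses
between the parametric branch (one-way ANOVA with pairwise Welch t tests)
and the nonparametric branch (Kruskal-Wallis with pairwise Wilcoxon
rank-sum tests); all pairwise families are Holm-adjusted. A permutation
t test (Welch statistic, label permutation without replacement, add-one
p-value estimator over 999 permutations by default) serves groups that are
unbalanced in both size and variance. Pairwise outcomes are rendered as a
compact letter display: groups sharing a letter are not significantly
different at alpha.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass
class ComparisonReport:
    groups: list[str]
    test_used: str            # anova+pairwise_t | kruskal+pairwise_wilcoxon
    global_p: float
    pairwise_p: pd.DataFrame  # Holm-adjusted, symmetric, unit diagonal
    letters: dict[str, str]
    alpha: float = 0.05


def _as_groups(groups_data: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups_data.items()}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def choose_branch(
    groups_data: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> str:
    """Normality gate: Shapiro-Wilk on pooled within-group residuals.

    p > alpha -> parametric; otherwise nonparametric. Any group with n < 3
    forces the nonparametric branch with a warning; all-constant data is
    degenerate and raises.
    """
    groups = _as_groups(groups_data)
    if any(len(v) < 3 for v in groups.values()):
        warnings.warn("group with n < 3: forcing nonparametric branch")
        return NONPARAMETRIC
    residuals = np.concatenate([v - v.mean() for v in groups.values()])
    if np.allclose(residuals, residuals[0]):
        raise ValueError("degenerate data: all residuals identical")
    p = stats.shapiro(residuals).pvalue
    return PARAMETRIC if p > alpha else NONPARAMETRIC


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = math.sqrt(vx / nx + vy / ny)
    diff = x.mean() - y.mean()
    if denom == 0:
        # both sides constant: infinitely strong separation unless equal
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation t test with the Welch statistic.

    Labels are permuted without replacement; the p-value uses the add-one
    estimator p = (1 + #{perm: |t_perm| >= |t_obs|}) / (n_perm + 1), so
    p is in [1/(n_perm+1), 1]. Zero pooled variance returns p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("zero pooled variance: permutation t test p = 1")
        return 1.0
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_obs = abs(_welch_t(x, y))
    nx = len(x)
    # vectorized label permutation: each row is one shuffled pooled sample
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    px, py = perm[:, :nx], perm[:, nx:]
    vx = px.var(axis=1, ddof=1)
    vy = py.var(axis=1, ddof=1)
    denom = np.sqrt(vx / nx + vy / len(y))
    diff = px.mean(axis=1) - py.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(
            denom == 0,
            np.where(diff == 0, 0.0, np.inf),
            diff / np.where(denom == 0, 1.0, denom),
        )
    n_extreme = int(np.sum(np.abs(t_perm) >= t_obs - 1e-12))
    return (1 + n_extreme) / (n_perm + 1)


def pairwise_tests(
    groups_data: Mapping[str, Sequence[float]], branch: str
) -> pd.DataFrame:
    """All k(k-1)/2 pairwise comparisons, Holm-adjusted across the family.

    Parametric branch: Welch t tests; nonparametric: Wilcoxon rank-sum
    (Mann-Whitney) with the normal approximation and tie correction.
    Returns a symmetric matrix with unit diagonal.
    """
    groups = _as_groups(groups_data)
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = []
    for a, b in pairs:
        if branch == PARAMETRIC:
            p = stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
        elif branch == NONPARAMETRIC:
            p = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="asymptotic"
            ).pvalue
        else:
            raise ValueError(f"unknown branch {branch!r}")
        raw.append(float(p))
    adjusted = (
        multipletests(raw, method="holm")[1] if len(raw) > 1 else np.asarray(raw)
    )
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adjusted):
        mat.loc[a, b] = mat.loc[b, a] = min(1.0, float(p))
    return mat


def _letter_symbols(n: int) -> list[str]:
    symbols = list(string.ascii_lowercase) + list(string.ascii_uppercase)
    while len(symbols) < n:
        symbols.append(symbols[len(symbols) % 52] + str(len(symbols) // 52))
    return symbols[:n]


def letter_display(
    pairwise_p_adj: pd.DataFrame,
    alpha: float = 0.05,
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two groups share at least one letter if and only if their adjusted p
    exceeds alpha. Intransitive significance patterns are handled by
    multi-letter assignment. ``order`` fixes the lettering order (callers
    typically pass groups sorted by median); by default the matrix order is
    used.
    """
    groups = [str(g) for g in pairwise_p_adj.index]
    if order is None:
        order = groups
    order = [str(g) for g in order]
    if set(order) != set(groups):
        raise ValueError("order must be a permutation of the matrix labels")

    letter_sets: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if pairwise_p_adj.loc[a, b] > alpha:
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another (incl. duplicates)
        absorbed: list[set[str]] = []
        for s in new_sets:
            if not s:
                continue
            if any(s < t or (s == t and s in absorbed) for t in new_sets if t is not s):
                continue
            if s in absorbed:
                continue
            absorbed.append(s)
        letter_sets = absorbed

    pos = {g: i for i, g in enumerate(order)}
    letter_sets.sort(key=lambda s: tuple(sorted(pos[g] for g in s)))
    symbols = _letter_symbols(len(letter_sets))
    letters = {g: "" for g in groups}
    for symbol, s in zip(symbols, letter_sets):
        for g in s:
            letters[g] += symbol
    return letters


def compare_groups(
    groups_data: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """Full scaffold: normality gate, global test, Holm-adjusted pairwise
    tests and the compact letter display (groups lettered by descending
    median)."""
    groups = _as_groups(groups_data)
    branch = choose_branch(groups, alpha=alpha)
    values = list(groups.values())
    if branch == PARAMETRIC:
        global_p = float(stats.f_oneway(*values).pvalue)
        test_used = "anova+pairwise_t"
    else:
        global_p = float(stats.kruskal(*values).pvalue)
        test_used = "kruskal+pairwise_wilcoxon"
    pairwise = pairwise_tests(groups, branch)
    order = sorted(groups, key=lambda g: -np.median(groups[g]))
    letters = letter_display(pairwise, alpha=alpha, order=order)
    return ComparisonReport(
        groups=list(groups),
        test_used=test_used,
        global_p=global_p,
        pairwise_p=pairwise,
        letters=letters,
        alpha=alpha,
    )
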