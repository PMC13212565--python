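"""Statistical scaffold: normality gate, permutation t test, pairwise
testing with Holm control, and the compact letter display."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from limnoscope.stats import (
    NONPARAMETRIC,
    PARAMETRIC,
    choose_branch,
    compare_groups,
    letter_display,
    pairwise_tests,
    permutation_t_test,
)


class TestChooseBranch:
    def test_heavy_tailed_goes_nonparametric(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.lognormal(0, 1.5, 50),
            "b": rng.lognormal(0.2, 1.5, 50),
        }
        assert choose_branch(groups) == NONPARAMETRIC

    def test_gaussian_goes_parametric(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(3, 1, 50)}
        assert choose_branch(groups) == PARAMETRIC

    def test_tiny_group_forces_nonparametric(self):
        with pytest.warns(UserWarning, match="n < 3"):
            branch = choose_branch({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert branch == NONPARAMETRIC

    def test_constant_groups_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            choose_branch({"a": [1.0] * 5, "b": [2.0] * 5})


class TestPermutationTTest:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert permutation_t_test(x, x, seed=0) == 1.0

    def test_perfect_separation_small_p(self):
        """x = 0^5 vs y = 10^5: only the label assignments reconstructing
        the split (2 of C(10,5) = 252) reach |t_obs|, so the exact
        permutation p is ~2/252 = 0.0079; the sampled estimate with 999
        draws must land at or below 0.01."""
        x, y = [0.0] * 5, [10.0] * 5
        # exhaustive enumeration oracle over all C(10,5) splits
        pooled = np.array(x + y)

        def welch(xs, ys):
            denom = math.sqrt(xs.var(ddof=1) / 5 + ys.var(ddof=1) / 5)
            diff = xs.mean() - ys.mean()
            if denom == 0:
                return 0.0 if diff == 0 else math.inf
            return abs(diff / denom)

        t_obs = welch(np.array(x), np.array(y))
        n_extreme = 0
        n_total = 0
        for idx in combinations(range(10), 5):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(10) if i not in idx]]
            n_total += 1
            n_extreme += welch(xs, ys) >= t_obs
        assert n_total == 252
        assert n_extreme == 2  # the two label assignments splitting 0s/10s
        p = permutation_t_test(x, y, n_perm=999, seed=0)
        assert p <= 0.01

    def test_p_value_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = permutation_t_test(
                rng.normal(size=6), rng.normal(size=9), seed=rng
            )
            assert 1 / 1000 <= p <= 1.0

    def test_zero_pooled_variance(self):
        with pytest.warns(UserWarning, match="variance"):
            assert permutation_t_test([1.0] * 4, [1.0] * 4, seed=0) == 1.0

    def test_seed_stability(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert permutation_t_test(x, y, seed=42) == permutation_t_test(
            x, y, seed=42
        )

    def test_null_type_i_error_calibrated(self):
        """Empirical type-I rate at nominal alpha = 0.05 over 500 null
        replicates (two N(0,1) samples, n = 10 each) lies in [0.03, 0.07]."""
        rng = np.random.default_rng(0)
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            hits += permutation_t_test(x, y, n_perm=999, seed=rng) <= 0.05
        assert 0.03 <= hits / n_reps <= 0.07


class TestPairwiseTests:
    def test_two_groups_adjustment_identity(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 1, 20)}
        adjusted = pairwise_tests(groups, PARAMETRIC)
        raw = sps.ttest_ind(groups["a"], groups["b"], equal_var=False).pvalue
        assert adjusted.loc["a", "b"] == pytest.approx(raw)

    def test_six_comparisons_clipped(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        mat = pairwise_tests(groups, NONPARAMETRIC)
        off_diag = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off_diag <= 1.0).all()
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_shifted_group_separates(self):
        """One group shifted by 5 sd (n = 30): Holm-adjusted p separates it
        from both others at alpha."""
        rng = np.random.default_rng(6)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": rng.normal(5, 1, 30),
        }
        mat = pairwise_tests(groups, PARAMETRIC)
        assert mat.loc["c", "a"] < 0.05
        assert mat.loc["c", "b"] < 0.05

    def test_holm_never_below_raw(self):
        rng = np.random.default_rng(7)
        groups = {k: rng.normal(0, 1, 12) for k in "abc"}
        adjusted = pairwise_tests(groups, PARAMETRIC)
        for a, b in combinations("abc", 2):
            raw = sps.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            assert adjusted.loc[a, b] >= raw - 1e-12


def _p_matrix(entries: dict[tuple[str, str], float], groups: str) -> pd.DataFrame:
    mat = pd.DataFrame(
        np.ones((len(groups), len(groups))), index=list(groups),
        columns=list(groups),
    )
    for (a, b), p in entries.items():
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


class TestLetterDisplay:
    def test_hand_worked_insert_absorb(self):
        mat = _p_matrix(
            {("a", "b"): 0.001, ("a", "c"): 0.001, ("b", "c"): 0.8}, "abc"
        )
        letters = letter_display(mat)
        assert letters["a"] == "a"
        assert letters["b"] == letters["c"] == "b"

    def test_all_non_significant_single_letter(self):
        mat = _p_matrix({(a, b): 0.9 for a, b in combinations("abcd", 2)}, "abcd")
        letters = letter_display(mat)
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        mat = _p_matrix({(a, b): 0.001 for a, b in combinations("abcd", 2)}, "abcd")
        letters = letter_display(mat)
        assert len(set(letters.values())) == 4
        assert all(len(v) == 1 for v in letters.values())

    def test_intransitive_pattern_multi_letter(self):
        # a != c but a ~ b and b ~ c: b must share with both
        mat = _p_matrix(
            {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.01}, "abc"
        )
        letters = letter_display(mat)
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_round_trip_on_random_matrices(self):
        """Letters regenerate exactly the thresholded significance relation
        on 100 random symmetric p matrices."""
        rng = np.random.default_rng(8)
        for rep in range(100):
            k = int(rng.integers(3, 7))
            groups = [f"g{i}" for i in range(k)]
            mat = pd.DataFrame(
                np.ones((k, k)), index=groups, columns=groups
            )
            for i, j in combinations(range(k), 2):
                p = float(rng.uniform(0, 1))
                mat.iloc[i, j] = mat.iloc[j, i] = p
            letters = letter_display(mat, alpha=0.05)
            for a, b in combinations(groups, 2):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (mat.loc[a, b] > 0.05), (rep, a, b)


class TestCompareGroups:
    def test_report_is_consistent(self):
        rng = np.random.default_rng(9)
        groups = {
            "a": rng.normal(0, 1, 25),
            "b": rng.normal(0.3, 1, 25),
            "c": rng.normal(4, 1, 25),
        }
        report = compare_groups(groups)
        assert report.test_used in (
            "anova+pairwise_t", "kruskal+pairwise_wilcoxon"
        )
        assert 0 <= report.global_p <= 1
        for x, y in combinations("abc", 2):
            share = bool(set(report.letters[x]) & set(report.letters[y]))
            assert share == (report.pairwise_p.loc[x, y] > report.alpha)
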