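"""Nonparametric statistics layer: Dunn vs. a permutation oracle, letter-display
axioms, exact Wilcoxon and Spearman values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thawnitro.stats import (
    compact_letters,
    dunn_pairwise,
    kruskal_dunn,
    paired_test,
    rank_correlation,
)


def permutation_pairwise_p(values, groups):
    """Oracle: exact permutation distribution of the pairwise mean-rank gap.

    Enumerates every assignment of the pooled values to the group layout and
    returns, per pair, the probability of a mean-rank difference at least as
    extreme as observed.
    """
    from scipy.stats import rankdata

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    ranks = rankdata(values)
    idx_by_group = {g: np.where(groups == g)[0] for g in labels}
    out = {}
    n = len(values)
    for g1, g2 in itertools.combinations(labels, 2):
        obs = abs(ranks[idx_by_group[g1]].mean() - ranks[idx_by_group[g2]].mean())
        n1, n2 = len(idx_by_group[g1]), len(idx_by_group[g2])
        count = total = 0
        for combo in itertools.combinations(range(n), n1):
            rest = [i for i in range(n) if i not in combo]
            for combo2 in itertools.combinations(rest, n2):
                stat = abs(ranks[list(combo)].mean() - ranks[list(combo2)].mean())
                count += stat >= obs - 1e-12
                total += 1
        out[(g1, g2)] = count / total
    return out


class TestKruskalDunn:
    def test_identical_groups_nothing_significant(self):
        values = [1, 2, 3, 1, 2, 3]
        groups = ["a"] * 3 + ["b"] * 3
        res = kruskal_dunn(values, groups)
        assert res.omnibus_stat == pytest.approx(0.0, abs=1e-9)
        assert not res.pairwise["significant"].any()
        assert set(res.letters.values()) == {"a"}

    def test_dunn_ordering_matches_permutation_oracle(self):
        values = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        pw = dunn_pairwise(np.array(values, float), np.array(groups))
        oracle = permutation_pairwise_p(values, groups)
        dunn_p = {(r.group1, r.group2): r.p_raw for r in pw.itertuples()}
        # the extreme pair (A, C) has the smallest p under both
        assert min(dunn_p, key=dunn_p.get) == ("A", "C")
        assert min(oracle, key=oracle.get) == ("A", "C")
        # p-value ordering agrees pair by pair
        order_d = sorted(dunn_p, key=dunn_p.get)
        order_o = sorted(oracle, key=oracle.get)
        assert [set(p) for p in order_d] == [set(p) for p in order_o]

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        r1 = kruskal_dunn(values, groups)
        r2 = kruskal_dunn(values + 1000.0, groups)
        assert r1.omnibus_stat == pytest.approx(r2.omnibus_stat)
        np.testing.assert_allclose(r1.pairwise["p_raw"], r2.pairwise["p_raw"])

    def test_all_tied_convention(self):
        res = kruskal_dunn([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.all_tied and res.omnibus_p == 1.0

    def test_adjusted_ge_raw(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        groups = np.repeat(list("abcd"), 5)
        for method in ("holm", "bonferroni"):
            res = kruskal_dunn(values, groups, adjust=method)
            assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_null_rejection_rate(self):
        """Type-I error of the omnibus test near alpha under the null."""
        rng = np.random.default_rng(123)
        alpha = 0.05
        n_sim = 1000
        rejections = 0
        groups = np.repeat(np.arange(5), 5)
        for _ in range(n_sim):
            values = rng.normal(size=25)
            rejections += kruskal_dunn(values, groups).omnibus_p < alpha
        # binomial 99.7% interval around 0.05 with n=1000: ~ +/- 0.021
        assert abs(rejections / n_sim - alpha) < 0.021

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1.0, 2.0], ["a", "a"])


class TestCompactLetters:
    def test_none_significant(self):
        sig = np.zeros((3, 3), bool)
        assert set(compact_letters(sig, ["x", "y", "z"]).values()) == {"a"}

    def test_all_significant(self):
        sig = ~np.eye(3, dtype=bool)
        letters = compact_letters(sig, ["x", "y", "z"])
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_pattern(self):
        # A != C, A = B, B = C -> A:a, B:ab, C:b
        sig = np.zeros((3, 3), bool)
        sig[0, 2] = sig[2, 0] = True
        letters = compact_letters(sig, ["A", "B", "C"])
        assert set(letters["A"]) & set(letters["C"]) == set()
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((2, 2), bool)
        sig[0, 1] = True
        with pytest.raises(ValueError):
            compact_letters(sig, ["a", "b"])

    @given(st.integers(min_value=2, max_value=7), st.integers(min_value=0, max_value=2**21 - 1))
    @settings(max_examples=200, deadline=None)
    def test_display_axioms_on_random_matrices(self, k, bits):
        """(i) significant pair -> disjoint letters; (ii) otherwise -> shared letter."""
        sig = np.zeros((k, k), bool)
        b = 0
        for i, j in itertools.combinations(range(k), 2):
            sig[i, j] = sig[j, i] = bool((bits >> b) & 1)
            b += 1
        groups = list(range(k))
        letters = compact_letters(sig, groups)
        assert all(letters[g] for g in groups)  # every group lettered
        for i, j in itertools.combinations(range(k), 2):
            shared = set(letters[i]) & set(letters[j])
            if sig[i, j]:
                assert not shared
            else:
                assert shared


class TestPairedTest:
    def test_degenerate_equal_vectors(self):
        stat, p, degenerate = paired_test([1, 2, 3], [1, 2, 3])
        assert degenerate and p == 1.0

    def test_exact_p_all_positive_n6(self):
        # all 6 differences positive: two-sided exact p = 2/2^6
        x = [10, 20, 30, 40, 50, 60]
        y = [9, 18, 27, 36, 45, 54]
        stat, p, degenerate = paired_test(x, y)
        assert not degenerate
        assert p == pytest.approx(2 / 64)
        assert stat == pytest.approx(21.0)  # sum of ranks 1..6

    def test_swap_flips_sign_same_p(self):
        x = [3.0, 5.0, 1.0, 9.0, 7.0]
        y = [2.0, 6.0, 0.5, 4.0, 8.0]
        s1, p1, _ = paired_test(x, y)
        s2, p2, _ = paired_test(y, x)
        assert s1 == -s2
        assert p1 == pytest.approx(p2)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_rank_arithmetic(self):
        # d^2 sum = 6 -> rho = 1 - 6*6/(5*24) = 0.7
        rho, p = rank_correlation([1, 2, 3, 4, 5], [2, 3, 1, 4, 5])
        assert rho == pytest.approx(0.7)
        # exact enumeration p: fraction of 5! permutations with |rho| >= 0.7
        assert 0 < p < 1

    def test_exact_p_matches_enumeration_n4(self):
        rho, p = rank_correlation([1, 2, 3, 4], [1, 2, 4, 3])
        # enumerate all 24 permutations by hand logic
        count = 0
        for perm in itertools.permutations([1, 2, 3, 4]):
            d2 = sum((a - b) ** 2 for a, b in zip(perm, [1, 2, 3, 4]))
            r = 1 - 6 * d2 / (4 * 15)
            count += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(count / 24)

    def test_symmetry(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [9.0, 2.0, 6.0, 5.0, 3.0]
        assert rank_correlation(x, y)[0] == pytest.approx(rank_correlation(y, x)[0])

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])
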