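"""Agreement statistics: Bland-Altman, kappa, ICC, Wilcoxon, McNemar."""

import itertools

import numpy as np
import pytest

from uldct.agreement import (
    bland_altman,
    cohen_kappa,
    icc,
    mcnemar,
    pooled_kappa,
    wilcoxon_signed_rank,
)
from uldct.errors import ArgumentError, UndefinedStatisticError


def exact_wilcoxon_p(diffs) -> tuple[float, float]:
    """Independent oracle: enumerate all sign assignments of the ranked
    absolute differences; two-sided p doubles the smaller tail."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = [sum(r for r, keep in zip(ranks, signs) if keep) for signs in itertools.product([0, 1], repeat=len(ranks))]
    ws = np.asarray(ws, dtype=float)
    p_lo = np.mean(ws <= w_obs)
    p_hi = np.mean(ws >= w_obs)
    return w_obs, min(1.0, 2 * min(p_lo, p_hi))


class TestBlandAltman:
    def test_zero_differences(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0 and res.lower_limit == 0 and res.upper_limit == 0 and res.range == 0

    def test_hand_computed_limits(self):
        # differences {1,2,3}: bias 2, SD 1 -> limits 2 -+ 1.96
        res = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(2.0)
        assert res.lower_limit == pytest.approx(0.04)
        assert res.upper_limit == pytest.approx(3.96)
        assert res.range == pytest.approx(3.92)

    def test_antisymmetry(self):
        a = np.array([3.0, 5.0, 9.0, 4.0])
        b = np.array([2.5, 6.0, 8.0, 4.5])
        fwd, rev = bland_altman(a, b), bland_altman(b, a)
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.range == pytest.approx(rev.range)

    def test_range_is_392_times_sd(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        res = bland_altman(a, b)
        assert res.range == pytest.approx(3.92 * np.std(a - b, ddof=1))

    def test_single_pair_rejected(self):
        with pytest.raises(ArgumentError):
            bland_altman([1.0], [2.0])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 2, 1, 2], [1, 2, 1, 2]) == 1.0

    def test_hand_computed_two_by_two(self):
        # confusion counts: yes/yes 20, yes/no 3, no/yes 2, no/no 5
        a = ["y"] * 20 + ["y"] * 3 + ["n"] * 2 + ["n"] * 5
        b = ["y"] * 20 + ["n"] * 3 + ["y"] * 2 + ["n"] * 5
        # p_o = 25/30, p_e = (23*22 + 7*8)/900 = 0.6244...
        assert cohen_kappa(a, b) == pytest.approx(0.556, abs=0.001)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_both_raters_constant_and_equal_is_one(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_pooled_namespaces_categories(self):
        # two tasks, each perfectly agreed -> pooled kappa 1
        assert pooled_kappa([([0, 1, 1], [0, 1, 1]), ([1, 0, 0], [1, 0, 0])]) == 1.0


class TestICC:
    def test_identical_vectors(self):
        assert icc([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_offset_penalized(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc(a, a + 10.0) < 0.5

    def test_variance_component_recovery(self):
        """Subject var 4, rater var 0.25, error var 0.25 ->
        ICC(2,1) = 4 / 4.5 ~= 0.889."""
        rng = np.random.default_rng(17)
        n = 200
        subject = rng.normal(0, 2.0, n)
        rater = rng.normal(0, 0.5, 2)
        a = subject + rater[0] + rng.normal(0, 0.5, n)
        b = subject + rater[1] + rng.normal(0, 0.5, n)
        assert icc(a, b) == pytest.approx(4.0 / 4.5, abs=0.05)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestWilcoxon:
    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)

    def test_exact_small_sample_vs_enumeration(self):
        w, p = wilcoxon_signed_rank([1.0, -2.0, 3.0])
        w_ref, p_ref = exact_wilcoxon_p([1.0, -2.0, 3.0])
        assert w == w_ref == 4.0
        assert p == pytest.approx(p_ref) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_enumeration_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.3, 1.0, 8), 2)
        d = d[d != 0]
        _, p = wilcoxon_signed_rank(d)
        _, p_ref = exact_wilcoxon_p(d)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_exact_and_approx_agree_at_crossover(self):
        rng = np.random.default_rng(33)
        d = rng.normal(0.4, 1.0, 25)
        _, p_exact = wilcoxon_signed_rank(d)  # n = 25 -> exact branch
        _, p_approx = wilcoxon_signed_rank(np.concatenate([d, [1e-12]]))  # n = 26 -> approx
        assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_p_distribution_sums_to_one_under_enumeration(self):
        """The exact sign-assignment distribution is a proper pmf."""
        from scipy.stats import rankdata

        d = np.array([0.5, -1.2, 2.0, 0.9, -0.3])
        ranks = rankdata(np.abs(d))
        total = 0.0
        counts = {}
        for signs in itertools.product([0, 1], repeat=len(ranks)):
            w = sum(r for r, keep in zip(ranks, signs) if keep)
            counts[w] = counts.get(w, 0) + 1
        total = sum(counts.values())
        assert total == 2 ** len(d)
        assert sum(c / total for c in counts.values()) == pytest.approx(1.0)


class TestMcNemar:
    def test_perfect_concordance(self):
        a = np.array([1] * 14 + [0] * 16, dtype=bool)
        b_counts, c_counts, p = mcnemar(a, a.copy())
        assert (b_counts, c_counts) == (0, 0)
        assert p == 1.0 > 0.99

    def test_five_discordant_one_direction(self):
        a = np.array([1] * 5 + [0] * 10 + [1] * 10)
        b = np.array([0] * 5 + [0] * 10 + [1] * 10)
        b_ct, c_ct, p = mcnemar(a, b)
        assert (b_ct, c_ct) == (5, 0)
        assert p == pytest.approx(2 * 0.5**5)

    def test_swapping_methods_swaps_counts_not_p(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        b1, c1, p1 = mcnemar(a, b)
        b2, c2, p2 = mcnemar(b, a)
        assert (b1, c1) == (c2, b2)
        assert p1 == pytest.approx(p2)

    def test_non_binary_rejected(self):
        with pytest.raises(ArgumentError):
            mcnemar([0, 1, 2], [0, 1, 1])
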