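"""Agreement and comparison statistics."""

import numpy as np
import pytest

from blinkwave.stats import (
    bland_altman,
    cohen_kappa,
    compare_groups,
    icc_absolute,
    spearman_corr,
)


class TestBlandAltman:
    def test_identical_measurements(self):
        rep = bland_altman([3.0, 5.0, 7.0], [3.0, 5.0, 7.0])
        assert rep.mean_diff == 0.0
        assert (rep.loa_low, rep.loa_high) == (0.0, 0.0)

    def test_hand_arithmetic_percent_mode(self):
        # d1 = 1/9.5*100 = 10.5263, d2 = -1/10.5*100 = -9.5238
        rep = bland_altman([10, 10], [9, 11], mode="percent")
        assert rep.mean_diff == pytest.approx(0.50, abs=0.005)
        assert rep.sd_diff == pytest.approx(10.025 * np.sqrt(2), abs=0.01)
        assert rep.loa_low == pytest.approx(-27.29, abs=0.01)
        assert rep.loa_high == pytest.approx(28.29, abs=0.01)

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            bland_altman([10], [9])

    def test_zero_mean_pairs_excluded(self):
        rep = bland_altman([1, -1, 2, 3], [1, 1, 2, 3], mode="percent")
        assert rep.n_used == 3

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(5, 10, 20)
        b = rng.uniform(5, 10, 20)
        r1 = bland_altman(a, b)
        r2 = bland_altman(b, a)
        assert r1.mean_diff == pytest.approx(-r2.mean_diff)
        assert r1.loa_low == pytest.approx(-r2.loa_high)
        assert r1.loa_high == pytest.approx(-r2.loa_low)

    def test_raw_mode(self):
        rep = bland_altman([10, 10], [9, 11], mode="raw")
        assert rep.mean_diff == 0.0


def icc2_closed_form(r: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares (independent oracle)."""
    n, k = r.shape
    grand = r.mean()
    msr = k * ((r.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((r.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((r - r.mean(axis=1, keepdims=True) - r.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters(self):
        assert icc_absolute(np.column_stack([[1, 2, 3], [1, 2, 3]])) == pytest.approx(1.0)

    def test_constant_ratings_error(self):
        with pytest.raises(ValueError):
            icc_absolute(np.full((4, 2), 3.0))

    def test_reversed_raters_match_closed_form(self):
        r = np.column_stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert icc_absolute(r) == pytest.approx(icc2_closed_form(r))
        assert icc_absolute(r) < 0

    def test_random_matrix_matches_closed_form(self):
        rng = np.random.default_rng(42)
        r = rng.normal(10, 2, size=(12, 2))
        assert icc_absolute(r) == pytest.approx(icc2_closed_form(r), abs=1e-9)


class TestKappa:
    def test_identical(self):
        assert cohen_kappa(list("aabb"), list("aabb")) == 1.0

    def test_perfect_disagreement(self):
        a = [0] * 5 + [1] * 5
        b = [1] * 5 + [0] * 5
        assert cohen_kappa(a, b) == pytest.approx(-1.0)

    def test_chance_agreement(self):
        # 2×2 table with all cells = 1: p_o = p_e = 0.5
        assert cohen_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        relabel = {0: "x", 1: "y", 2: "z"}
        k1 = cohen_kappa(a, b)
        k2 = cohen_kappa([relabel[i] for i in a], [relabel[i] for i in b])
        assert k1 == pytest.approx(k2)


class TestSpearman:
    def test_monotone(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        rho, _ = spearman_corr([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == -1.0

    def test_hand_example(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestCompareGroups:
    def test_identical_normal_samples(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0, 1, 30)
        name, stat, p = compare_groups(g, g)
        assert name == "t-test"
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_detects_two_sd_shift(self):
        rng = np.random.default_rng(7)
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(2, 1, 50)
        _, _, p = compare_groups(g1, g2)
        assert p < 0.05

    def test_skewed_data_uses_mannwhitney(self):
        rng = np.random.default_rng(3)
        g1 = rng.exponential(1, 80)
        g2 = rng.exponential(1, 80)
        name, _, _ = compare_groups(g1, g2)
        assert name == "mann-whitney"

    def test_undersized_group(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [1, 2, 3])
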