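import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ferrocup as fc
from ferrocup.stats import significance_code
from oracles import bh_bruteforce, ranksum_exact_p_bruteforce


class TestWilcoxonRankSum:
    def test_separated_triplets_exact_p(self):
        res = fc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = fc.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pooled = rng.choice(1000, size=n_a + n_b, replace=False).astype(float)
            a, b = pooled[:n_a], pooled[n_a:]
            res = fc.wilcoxon_rank_sum(a, b)
            assert res.exact
            assert res.p == pytest.approx(ranksum_exact_p_bruteforce(a, b))

    def test_ties_force_asymptotic_path(self):
        res = fc.wilcoxon_rank_sum([1.0, 1.0, 2.0], [3.0, 4.0, 5.0])
        assert not res.exact

    def test_large_n_forces_asymptotic_path(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert not fc.wilcoxon_rank_sum(a, b).exact

    def test_asymptotic_close_to_exact_where_both_defined(self, rng):
        for _ in range(20):
            pooled = rng.choice(10_000, size=12, replace=False).astype(float)
            a, b = pooled[:6], pooled[6:]
            exact = fc.wilcoxon_rank_sum(a, b).p
            approx = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fc.wilcoxon_rank_sum([], [1.0])


class TestKruskalWallis:
    def test_two_groups_equals_squared_ranksum_z(self, rng):
        """With two groups, tie-corrected H equals the squared tie-corrected
        normal-approximation z of the rank-sum statistic."""
        for _ in range(10):
            a = np.round(rng.normal(size=8), 1)
            b = np.round(rng.normal(size=6), 1)
            h = fc.kruskal_wallis([a, b]).statistic
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            n, n_a = pooled.size, a.size
            w = ranks[:n_a].sum()
            mu = n_a * (n + 1) / 2.0
            _, counts = np.unique(pooled, return_counts=True)
            tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
            var = n_a * (n - n_a) / 12.0 * (n + 1 - tie_term)
            z = (w - mu) / np.sqrt(var)
            assert h == pytest.approx(z**2, rel=1e-9)

    def test_identical_groups_degenerate(self):
        res = fc.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p == 1.0 and res.degenerate

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=7), rng.normal(size=6)]
        h1 = fc.kruskal_wallis(groups).statistic
        h2 = fc.kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            fc.kruskal_wallis([[1.0, 2.0]])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = fc.pearson_test(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)
        assert 0 < res.p <= 1e-6

    def test_orthogonal_vectors_n4(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        res = fc.pearson_test(x, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert fc.pearson_test(x, y).statistic == pytest.approx(
            fc.pearson_test(y, x).statistic
        )

    def test_constant_vector_degenerate(self):
        res = fc.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.statistic == 0.0 and res.p == 1.0


class TestBHAdjust:
    def test_single_p_identity(self):
        assert fc.bh_adjust([0.01]).tolist() == [0.01]

    def test_hand_computed_stepup(self):
        out = fc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_sorted_input_gives_sorted_output(self, rng):
        p = np.sort(rng.uniform(0.001, 1.0, size=15))
        out = fc.bh_adjust(p)
        assert (np.diff(out) >= -1e-12).all()

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0.0001, 1.0, size=int(rng.integers(1, 21)))
            np.testing.assert_allclose(fc.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0.0001, 1.0, size=40)
        assert (fc.bh_adjust(p) >= p - 1e-15).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_property_matches_oracle_and_dominates_raw(self, p):
        out = fc.bh_adjust(p)
        np.testing.assert_allclose(out, bh_bruteforce(p), atol=1e-12)
        assert (out >= np.asarray(p) - 1e-15).all()
        assert (out <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fc.bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            fc.bh_adjust([1.5])


def test_significance_codes_match_thresholds():
    assert significance_code(0.2) == "ns"
    assert significance_code(0.04) == "*"
    assert significance_code(0.009) == "**"
    assert significance_code(0.0009) == "***"
    assert significance_code(0.00009) == "****"
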