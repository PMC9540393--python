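import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leica.entropy import (
    EntropyProfile,
    adjust_pvalues,
    compare_groups,
    entropy_profiles,
    hedges_g,
    permutation_diff_means,
    shannon_entropy,
)


class TestShannonEntropy:
    def test_uniform_eight_bins_discrete(self):
        x = np.repeat(np.arange(8), 125).astype(float)
        h = shannon_entropy(x, estimator="discrete", n_bins=8)
        assert h == pytest.approx(math.log(8), abs=1e-12)

    def test_constant_discrete_is_zero(self):
        assert shannon_entropy(np.full(100, 2.5), estimator="discrete") == 0.0

    def test_constant_differential_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.full(100, 2.5), estimator="differential")

    def test_log_base_two(self):
        x = np.repeat(np.arange(8), 125).astype(float)
        h = shannon_entropy(x, estimator="discrete", n_bins=8, log_base=2)
        assert h == pytest.approx(3.0, abs=1e-12)

    def test_scale_shifts_differential_entropy_by_log(self, rng):
        # h(aX) = h(X) + log a for differential entropy
        x = rng.standard_normal(50_000)
        h1 = shannon_entropy(x, n_bins=64)
        h2 = shannon_entropy(3.0 * x, n_bins=64)
        assert h2 - h1 == pytest.approx(math.log(3.0), abs=0.01)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.0, 2.0, 3.0])

    @given(st.integers(2, 64), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_discrete_entropy_bounded(self, bins, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        h = shannon_entropy(x, estimator="discrete", n_bins=bins)
        assert 0.0 <= h <= math.log(bins) + 1e-12


class TestEntropyProfiles:
    def test_joint_is_exact_sum(self, rng):
        sources = rng.standard_normal((12, 200))
        profiles = entropy_profiles(sources, [(0, 100), (100, 200)])
        for p in profiles:
            assert p.joint == np.sum(p.per_component)  # bitwise
            assert p.per_component.size == 12

    def test_additivity_under_component_change(self, rng):
        sources = rng.standard_normal((3, 100))
        p0 = entropy_profiles(sources, [(0, 100)])[0]
        doubled = sources.copy()
        doubled[0] *= math.e  # raises component-0 differential entropy by 1 nat
        p1 = entropy_profiles(doubled, [(0, 100)])[0]
        dh = p1.per_component[0] - p0.per_component[0]
        assert p1.joint - p0.joint == pytest.approx(dh, abs=1e-12)

    def test_constant_sources_discrete_joint_zero(self):
        sources = np.ones((4, 64))
        profiles = entropy_profiles(sources, [(0, 64)], estimator="discrete")
        assert profiles[0].joint == 0.0

    def test_boundaries_must_partition(self, rng):
        sources = rng.standard_normal((2, 100))
        with pytest.raises(ValueError):
            entropy_profiles(sources, [(0, 40), (50, 100)])

    def test_empty_range_rejected(self, rng):
        sources = rng.standard_normal((2, 100))
        with pytest.raises(ValueError):
            entropy_profiles(sources, [(0, 0), (0, 100)])


class TestPermutationTest:
    def test_identical_samples_p_one(self):
        a = np.arange(10.0)
        assert permutation_diff_means(a, a.copy(), n_perm=500, seed=0) == 1.0

    def test_huge_separation_minimum_p(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 20.0  # ~10 pooled SDs
        n_perm = 2000
        p = permutation_diff_means(a, b, n_perm=n_perm, seed=1)
        assert p == pytest.approx(1.0 / (n_perm + 1))

    def test_deterministic_given_seed(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15) + 0.5
        p1 = permutation_diff_means(a, b, n_perm=999, seed=7)
        p2 = permutation_diff_means(a, b, n_perm=999, seed=7)
        assert p1 == p2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            permutation_diff_means([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            permutation_diff_means([1.0, 2.0], [1.0, 2.0], n_perm=0)

    def test_null_p_values_uniform(self, rng):
        # Kolmogorov-Smirnov check on replicate null tests
        from scipy.stats import kstest

        n_rep, n_perm = 2000, 199
        pvals = np.empty(n_rep)
        for i in range(n_rep):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            pvals[i] = permutation_diff_means(a, b, n_perm=n_perm, seed=rng)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestHedgesG:
    def test_hand_computed_example(self):
        # means 1 and 2, both sample variances 1, pooled SD 1,
        # J = 1 - 3/(4*6 - 9) = 0.8 -> g = 0.8 * (1 - 2) = -0.8
        assert hedges_g([0, 1, 2], [1, 2, 3]) == pytest.approx(-0.8, abs=1e-12)

    def test_equal_means_zero(self, rng):
        a = rng.standard_normal(30)
        assert hedges_g(a, a[::-1]) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(25) + 1
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [1.0, 1.0])


class TestPvalueAdjustment:
    def test_single_p_unchanged(self):
        for method in ("fdr_bh", "sidak", "bonferroni"):
            adj, rej = adjust_pvalues([0.03], method=method)
            assert adj[0] == pytest.approx(0.03)
            assert rej[0]

    def test_fdr_step_up_example(self):
        # BH: max i with p_(i) <= i/m * alpha is i = 4 -> all rejected
        adj, rej = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="fdr_bh", alpha=0.05)
        assert rej.all()

    def test_all_ones_no_rejection(self):
        adj, rej = adjust_pvalues([1.0, 1.0, 1.0])
        assert not rej.any()
        assert (adj == 1.0).all()

    def test_conservative_methods_dominate_raw(self, rng):
        p = rng.uniform(0.001, 1.0, 20)
        for method in ("sidak", "bonferroni"):
            adj, _ = adjust_pvalues(p, method=method)
            assert (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])


class TestGroupComparison:
    def test_shapes_and_signs(self, rng):
        k = 4
        g1 = [EntropyProfile(f"a{i}", rng.standard_normal(k) + 1) for i in range(8)]
        g2 = [EntropyProfile(f"b{i}", rng.standard_normal(k)) for i in range(8)]
        c = compare_groups(g1, g2, n_perm=500, seed=0)
        assert c.statistic.shape == (k,)
        assert (c.p_values > 0).all() and (c.p_values <= 1).all()
        assert c.statistic.mean() > 0  # group1 larger by construction
        assert c.effect_sizes.mean() > 0
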