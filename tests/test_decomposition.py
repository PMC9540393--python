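import numpy as np
import pytest
from scipy.stats import norm

from leica.decomposition import (
    component_core_regions,
    count_significant_dimensions,
    fit_ica,
    mp_upper_bound,
    project_sources,
)


class TestMPBound:
    def test_q4_upper_edge(self):
        b = mp_upper_bound(m=100, n=400, sigma2=1.0)
        assert b.lambda_max == pytest.approx(2.25)
        assert b.lambda_min == pytest.approx(0.25)

    def test_large_q_limit(self):
        b = mp_upper_bound(m=10, n=10_000_000)
        assert b.lambda_max == pytest.approx(1.0, abs=3e-3)

    def test_square_case_with_scale(self):
        b = mp_upper_bound(m=50, n=50, sigma2=2.0)
        assert b.lambda_max == pytest.approx(8.0)
        assert b.lambda_min == pytest.approx(0.0)

    def test_wrong_orientation_rejected(self):
        with pytest.raises(ValueError):
            mp_upper_bound(m=400, n=100)


class TestDimensionCount:
    def test_rank_one_duplicated_rows(self, rng):
        row = rng.standard_normal(500)
        x = np.vstack([row + 1e-6 * rng.standard_normal(500) for _ in range(8)])
        assert count_significant_dimensions(x) == 1

    def test_constant_row_rejected(self, rng):
        x = rng.standard_normal((5, 100))
        x[2] = 4.2
        with pytest.raises(ValueError):
            count_significant_dimensions(x)

    def test_wide_orientation_required(self, rng):
        with pytest.raises(ValueError):
            count_significant_dimensions(rng.standard_normal((100, 30)))

    def test_monotone_in_signal_strength(self, rng):
        # planted low-rank structure: k never decreases as the planted
        # component strength grows
        n, t = 12, 2000
        patterns = rng.standard_normal((3, n))
        activity = rng.standard_normal((3, t))
        noise = rng.standard_normal((n, t))
        ks = []
        for strength in (0.0, 0.3, 0.8, 2.0):
            x = noise + strength * patterns.T @ activity
            ks.append(count_significant_dimensions(x))
        assert ks == sorted(ks)
        assert ks[0] == 0 and ks[-1] == 3


class TestICA:
    @staticmethod
    def _mixed_sources(rng, k=3, n=8, t=5000):
        s = rng.uniform(-np.sqrt(3), np.sqrt(3), (k, t))  # independent, non-Gaussian
        a = rng.standard_normal((n, k))
        return a @ s, s

    def test_recovers_independent_sources(self, rng):
        x, s_true = self._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        # match recovered to true sources up to permutation and sign
        corr = np.abs(np.corrcoef(dec.sources, s_true)[:3, 3:])
        assert (corr.max(axis=1) >= 0.95).all()
        assert (corr.max(axis=0) >= 0.95).all()

    def test_sources_standardized_and_decorrelated(self, rng):
        x, _ = self._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=1)
        assert np.allclose(dec.sources.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(dec.sources.std(axis=1), 1.0, atol=1e-10)
        c = np.corrcoef(dec.sources)
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() <= 0.05

    def test_mixing_reconstructs_input(self, rng):
        x, _ = self._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        recon = dec.mixing @ dec.sources + dec.row_means[:, None]
        err = np.linalg.norm(recon - x) / np.linalg.norm(x)
        assert err <= 0.05

    def test_single_component_is_leading_pc(self, rng):
        x, _ = self._mixed_sources(rng, k=2)
        dec = fit_ica(x, 1, seed=0)
        xc = x - x.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        corr = np.corrcoef(dec.sources[0], vt[0])[0, 1]
        assert abs(corr) >= 0.999

    def test_deterministic_given_seed(self, rng):
        x, _ = self._mixed_sources(rng)
        d1 = fit_ica(x, 3, seed=5)
        d2 = fit_ica(x, 3, seed=5)
        assert np.array_equal(d1.sources, d2.sources)
        assert np.array_equal(d1.mixing, d2.mixing)

    def test_ordered_by_mean_absolute_activity(self, rng):
        x, _ = self._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        activity = np.mean(np.abs(dec.sources), axis=1)
        assert (np.diff(activity) <= 1e-12).all()

    def test_k_out_of_range(self, rng):
        x, _ = self._mixed_sources(rng)
        with pytest.raises(ValueError):
            fit_ica(x, 0, seed=0)


class TestCoreRegions:
    def test_normal_tail_fraction(self, rng):
        fractions = []
        for _ in range(200):
            maps = rng.standard_normal((200, 1))
            core = component_core_regions(maps, z_threshold=1.3)[0]
            fractions.append((core["positive"].size + core["negative"].size) / 200)
        expected = 2 * (1 - norm.cdf(1.3))
        assert np.mean(fractions) == pytest.approx(expected, abs=0.02)

    def test_constant_map_empty_core(self):
        with pytest.warns(RuntimeWarning):
            core = component_core_regions(np.ones((10, 1)))[0]
        assert core["positive"].size == 0 and core["negative"].size == 0

    def test_zero_threshold_returns_all_nonzero(self, rng):
        maps = rng.standard_normal((50, 1))
        core = component_core_regions(maps, z_threshold=0.0)[0]
        z = core["z"]
        assert core["positive"].size + core["negative"].size == np.sum(z != 0)

    def test_signs_partition_core(self, rng):
        maps = rng.standard_normal((100, 2))
        for core in component_core_regions(maps):
            assert not set(core["positive"]) & set(core["negative"])


class TestProjection:
    def test_training_data_reproduces_sources(self, rng):
        x, _ = TestICA._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        assert np.allclose(project_sources(dec, x), dec.sources, atol=1e-8)

    def test_zero_input_constant_output(self, rng):
        x, _ = TestICA._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        out = project_sources(dec, np.zeros_like(x))
        assert np.allclose(out, out[:, :1])

    def test_column_permutation_equivariant(self, rng):
        x, _ = TestICA._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        perm = rng.permutation(x.shape[1])
        assert np.allclose(
            project_sources(dec, x[:, perm]), project_sources(dec, x)[:, perm]
        )

    def test_linear_without_centering(self, rng):
        x, _ = TestICA._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        y = rng.standard_normal(x.shape)
        lhs = project_sources(dec, 2.0 * x + 3.0 * y, center=False)
        rhs = 2.0 * project_sources(dec, x, center=False) + 3.0 * project_sources(
            dec, y, center=False
        )
        assert np.allclose(lhs, rhs)

    def test_row_mismatch_rejected(self, rng):
        x, _ = TestICA._mixed_sources(rng)
        dec = fit_ica(x, 3, seed=0)
        with pytest.raises(ValueError):
            project_sources(dec, rng.standard_normal((5, 10)))
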