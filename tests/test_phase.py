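import numpy as np
import pytest

from leica.io import RegionalTimeSeries
from leica.phase import (
    DegenerateSignalError,
    alternative_representation,
    bandpass_filter,
    coherence_matrix,
    eigenvector_series,
    instantaneous_phase,
    leading_eigenvector,
)


def _ts(values, tr=2.0):
    return RegionalTimeSeries(values=np.atleast_2d(values), tr=tr)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        tr = 2.0
        t = np.arange(600) * tr
        x = np.sin(2 * np.pi * 0.045 * t)  # band centre
        y = bandpass_filter(_ts(np.vstack([x, x]), tr), 0.01, 0.08).values[0]
        inner = slice(50, 550)
        assert abs(y[inner].std() / x[inner].std() - 1) < 0.05

    def test_stopband_attenuated(self):
        # two octaves above the high edge; interior samples exclude the
        # forward-backward filter's edge transients
        tr = 0.5
        t = np.arange(2400) * tr
        x = np.sin(2 * np.pi * 0.32 * t)
        y = bandpass_filter(_ts(np.vstack([x, x]), tr), 0.01, 0.08).values[0]
        inner = slice(200, 2200)
        assert y[inner].std() < 0.10 * x[inner].std()

    def test_constant_removed(self):
        out = bandpass_filter(_ts(np.full((2, 100), 3.0)), 0.01, 0.08)
        assert np.abs(out.values).max() < 1e-10

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_ts(np.random.default_rng(0).normal(size=(2, 100))), 0.01, 0.3)


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        tr = 2.0
        t = np.arange(600) * tr
        x = np.cos(2 * np.pi * 0.05 * t)
        theta = instantaneous_phase(_ts(np.vstack([x, x]), tr)).theta[0]
        slope = np.diff(np.unwrap(theta))[100:500].mean() / tr
        assert abs(slope / (2 * np.pi * 0.05) - 1) < 0.01

    def test_identical_rows_identical_phase(self, rng):
        x = rng.standard_normal(64)
        ph = instantaneous_phase(_ts(np.vstack([x, x])))
        assert np.array_equal(ph.theta[0], ph.theta[1])

    def test_sin_cos_quarter_cycle_offset(self, sine_ts):
        ph = instantaneous_phase(sine_ts)
        off = (np.unwrap(ph.theta[0]) - np.unwrap(ph.theta[1]))[100:500]
        assert off.mean() == pytest.approx(np.pi / 2, abs=0.01)
        assert np.allclose(off, np.pi / 2, atol=0.02)

    def test_zero_row_rejected(self):
        values = np.vstack([np.zeros(64), np.random.default_rng(0).normal(size=64)])
        with pytest.raises(DegenerateSignalError):
            instantaneous_phase(_ts(values))

    def test_edge_samples_flagged(self, sine_ts):
        ph = instantaneous_phase(sine_ts)
        k = int(np.ceil(sine_ts.n_timepoints / 20))
        assert ph.edge_flags[:k].all() and ph.edge_flags[-k:].all()
        assert not ph.edge_flags[k:-k].any()


class TestCoherenceMatrix:
    def test_matches_double_loop_oracle(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (8, 20))
        for t in range(20):
            m = coherence_matrix(theta, t)
            oracle = np.empty((8, 8))
            for i in range(8):
                for j in range(8):
                    oracle[i, j] = np.cos(theta[i, t] - theta[j, t])
            assert np.abs(m - oracle).max() <= 1e-12

    def test_in_phase_gives_ones(self):
        theta = np.full((5, 3), 0.7)
        assert np.array_equal(coherence_matrix(theta, 1), np.ones((5, 5)))

    def test_antiphase_gives_minus_one(self):
        theta = np.array([[0.0], [np.pi]])
        m = coherence_matrix(theta, 0)
        assert m[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_quadrature_gives_zero(self):
        theta = np.array([[0.0], [np.pi / 2]])
        assert coherence_matrix(theta, 0)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_at_most_two(self, rng):
        for _ in range(200):
            theta = rng.uniform(-np.pi, np.pi, (12, 1))
            eigs = np.linalg.eigvalsh(coherence_matrix(theta, 0))
            assert abs(sorted(np.abs(eigs))[-3]) <= 1e-8 * np.abs(eigs).max()

    def test_out_of_range_timepoint(self):
        with pytest.raises(IndexError):
            coherence_matrix(np.zeros((3, 5)), 5)


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v1, rho = leading_eigenvector(np.ones((6, 6)))
        assert np.allclose(np.abs(v1), 1 / np.sqrt(6))
        assert rho == pytest.approx(1.0)
        assert (v1 <= 0).sum() > 3  # sign convention

    def test_rho_at_least_half_on_phase_matrices(self, rng):
        for _ in range(100):
            theta = rng.uniform(-np.pi, np.pi, (15, 1))
            _, rho = leading_eigenvector(coherence_matrix(theta, 0))
            assert rho >= 0.5

    def test_two_block_phases_split_by_sign(self):
        theta = np.concatenate([np.zeros(4), np.full(4, np.pi)])[:, None]
        v1, _ = leading_eigenvector(coherence_matrix(theta, 0))
        assert np.allclose(np.abs(v1), 1 / np.sqrt(8))
        assert len(set(np.sign(v1[:4]))) == 1
        assert np.sign(v1[0]) == -np.sign(v1[4])

    def test_sign_convention_idempotent(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (9, 1))
        m = coherence_matrix(theta, 0)
        v1, _ = leading_eigenvector(m)
        v2, _ = leading_eigenvector(m.copy())
        assert np.array_equal(v1, v2)
        assert (v1 <= 0).sum() * 2 >= v1.size


class TestEigenvectorSeries:
    def test_subject_blocks_and_shapes(self, small_cohort):
        ev = eigenvector_series(small_cohort[:3])
        assert ev.E.shape == (10, 3 * 120)
        assert ev.subject_boundaries == [(0, 120), (120, 240), (240, 360)]
        assert np.allclose(np.linalg.norm(ev.E, axis=0), 1.0)
        assert (ev.rho >= 0.5).all()

    def test_identical_subjects_identical_blocks(self, small_cohort):
        ts = small_cohort[0]
        ev = eigenvector_series([ts, ts])
        assert np.array_equal(ev.E[:, :120], ev.E[:, 120:])

    def test_heterogeneous_regions_rejected(self, small_cohort, rng):
        other = RegionalTimeSeries(values=rng.standard_normal((5, 120)), tr=2.0)
        with pytest.raises(ValueError):
            eigenvector_series([small_cohort[0], other])


class TestAlternativeRepresentations:
    def test_vectorized_pair_order(self):
        theta = np.array([[0.0], [0.1], [0.2], [0.3]])
        x, bounds = alternative_representation([_phases(theta)], "vectorized")
        assert x.shape == (6, 1)
        m = coherence_matrix(theta, 0)
        expected = [m[0, 1], m[0, 2], m[0, 3], m[1, 2], m[1, 3], m[2, 3]]
        assert np.allclose(x[:, 0], expected)
        assert bounds == [(0, 1)]

    def test_spatial_mean_of_in_phase(self):
        theta = np.full((5, 2), 1.0)
        x, _ = alternative_representation([_phases(theta)], "spatial_mean")
        assert np.allclose(x, 1.0)

    def test_unknown_kind_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            alternative_representation(small_cohort[:1], "pca")


def _phases(theta):
    from leica.phase import PhaseSeries

    return PhaseSeries(theta=theta, tr=2.0)
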