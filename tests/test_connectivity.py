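"""Coherence estimation, band matrices and network binarization."""

import math

import numpy as np
import pytest
from scipy import signal as spsig

from hippoconn.connectivity import (
    BinaryNetwork,
    ConnectivityError,
    DegenerateEstimateError,
    SpectralParams,
    band_coherence_matrices,
    band_coherence_matrix,
    binarize,
    coherence,
    welch_spectra,
)
from hippoconn.preprocess import BandDefinition, SOISegment
from hippoconn.synthetic import band_limited_noise

FS = 2000.0


def seg(samples: np.ndarray, fs: float = FS) -> SOISegment:
    return SOISegment(
        trial_id=0,
        phase="acquisition",
        samples=samples,
        t_start_s=0.0,
        t_end_s=samples.shape[0] / fs,
        sampling_rate_hz=fs,
        channel_labels=[f"ch{i:02d}" for i in range(samples.shape[1])],
    )


class TestWelchSpectra:
    def test_auto_equals_cross_for_identical_inputs(self):
        x = np.random.default_rng(0).standard_normal(8000)
        est = welch_spectra(x, x, FS)
        assert np.allclose(est.p_xy.real, est.p_x, rtol=1e-12, atol=0)
        assert np.max(np.abs(est.p_xy.imag)) < 1e-15 * est.p_x.max()
        assert np.array_equal(est.p_x, est.p_y)

    def test_sinusoid_auto_spectrum_peaks_at_its_frequency(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        est = welch_spectra(x, x, FS, window_s=1.0)
        peak_bin = int(np.argmax(est.p_x))
        assert est.frequencies[peak_bin] == pytest.approx(10.0)

    def test_cauchy_schwarz_bound_over_seeded_draws(self):
        for k in range(1000):
            rng = np.random.default_rng(k)
            x = rng.standard_normal(600)
            y = 0.5 * x + rng.standard_normal(600)
            est = welch_spectra(x, y, fs=100.0, window_s=2.0, overlap=0.5)
            assert (np.abs(est.p_xy) ** 2 <= est.p_x * est.p_y).all()

    def test_single_window_refused(self):
        x = np.zeros(2100)
        with pytest.raises(DegenerateEstimateError):
            welch_spectra(x, x, FS, window_s=1.0, overlap=0.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConnectivityError):
            welch_spectra(np.zeros(4000), np.zeros(4001), FS)


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(42000)  # ~20 windows of 1 s at 50% overlap
        coh = coherence(welch_spectra(x, x, FS))
        assert np.max(np.abs(coh.coherence - 1.0)) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10000)
        c1 = coherence(welch_spectra(x, 3.0 * x, FS)).coherence
        assert np.max(np.abs(c1 - 1.0)) < 1e-9

    def test_independent_noise_bias_matches_one_over_n(self):
        # E[coherence] = 1/n for independent Gaussian inputs and n
        # independent (non-overlapping) averaged windows
        rng = np.random.default_rng(1234)
        n_windows = 16
        means = []
        for _ in range(200):
            x = rng.standard_normal(n_windows * 2000)
            y = rng.standard_normal(n_windows * 2000)
            coh = coherence(welch_spectra(x, y, FS, window_s=1.0, overlap=0.0))
            means.append(coh.coherence[1:-1].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(means.size)
        assert abs(means.mean() - 1.0 / n_windows) < 3 * se

    def test_matches_scipy_estimator(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12000)
        y = 0.4 * x + rng.standard_normal(12000)
        coh = coherence(welch_spectra(x, y, FS, window_s=1.0, overlap=0.5))
        f_sp, c_sp = spsig.coherence(
            x, y, fs=FS, nperseg=2000, noverlap=1000, window="hann", detrend=False
        )
        assert np.allclose(coh.frequencies, f_sp)
        assert np.allclose(coh.coherence, c_sp, atol=1e-10)

    def test_zero_power_bins_flagged_not_nan(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 10 * t)  # zero power in most bins
        coh = coherence(welch_spectra(x, x, FS))
        assert np.isfinite(coh.coherence).all()


class TestBandCoherenceMatrix:
    def test_identical_channels_give_unit_matrix(self, theta):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(8000)
        mat = band_coherence_matrix(seg(np.column_stack([x, x])), theta)
        assert np.allclose(mat.matrix, 1.0, atol=1e-9)

    def test_matches_straight_line_reimplementation(self, theta):
        """A no-shortcuts pairwise oracle: loop windows, average FFT products,
        form |p_xy|^2/(p_x p_y), average the in-band bins."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6000, 4))
        params = SpectralParams(window_s=1.0, overlap=0.5)
        mat = band_coherence_matrix(seg(x), theta, params)

        nper, hop = 2000, 1000
        taper = spsig.get_window("hann", nper)
        starts = range(0, x.shape[0] - nper + 1, hop)
        ffts = [
            np.stack([np.fft.rfft(x[s : s + nper, c] * taper) for s in starts])
            for c in range(4)
        ]
        freqs = np.fft.rfftfreq(nper, d=1.0 / FS)
        band = (freqs >= theta.lo_hz) & (freqs <= theta.hi_hz)
        expected = np.eye(4)
        for i in range(4):
            for j in range(i + 1, 4):
                pxy = (ffts[i] * ffts[j].conj()).mean(axis=0)
                px = (np.abs(ffts[i]) ** 2).mean(axis=0)
                py = (np.abs(ffts[j]) ** 2).mean(axis=0)
                c = (np.abs(pxy) ** 2 / (px * py))[band].mean()
                expected[i, j] = expected[j, i] = c
        assert np.allclose(mat.matrix, expected, atol=1e-12)

    def test_permutation_equivariance(self, theta):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((6000, 5))
        perm = np.array([3, 0, 4, 1, 2])
        m1 = band_coherence_matrix(seg(x), theta).matrix
        m2 = band_coherence_matrix(seg(x[:, perm]), theta).matrix
        assert np.allclose(m2, m1[np.ix_(perm, perm)], atol=1e-12)

    def test_planted_group_raises_within_group_coherence(self, theta):
        rng = np.random.default_rng(7)
        n = 8000
        within, between = [], []
        for _ in range(50):
            shared = band_limited_noise(rng, n, FS, 5, 12)
            cols = []
            for c in range(6):
                private = band_limited_noise(rng, n, FS, 5, 12)
                if c < 3:  # channels 0-2 share the theta source
                    cols.append(math.sqrt(0.8) * shared + math.sqrt(0.2) * private)
                else:
                    cols.append(private)
            mat = band_coherence_matrix(seg(np.column_stack(cols)), theta).matrix
            within.append(np.mean([mat[0, 1], mat[0, 2], mat[1, 2]]))
            between.append(mat[np.ix_([0, 1, 2], [3, 4, 5])].mean())
        assert np.mean(within) > np.mean(between) + 0.3

    def test_band_without_bins_is_an_error(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((6000, 2))
        narrow = BandDefinition("narrow", 10.2, 10.4)  # between 1-Hz bins
        with pytest.raises(ConnectivityError, match="longer window"):
            band_coherence_matrix(seg(x), narrow)

    def test_multi_band_path_equals_single_band(self, theta):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((6000, 3))
        delta = BandDefinition("delta", 1.0, 4.0)
        multi = band_coherence_matrices(seg(x), [delta, theta])
        assert np.allclose(multi[1].matrix, band_coherence_matrix(seg(x), theta).matrix)
        assert np.allclose(multi[0].matrix, band_coherence_matrix(seg(x), delta).matrix)


class TestBinarize:
    def test_positive_matrix_zero_threshold_complete(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(0.1, 1.0, size=(16, 16))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        net = binarize(m, "absolute", 0.0)
        assert net.n_edges == 16 * 15 // 2

    def test_proportional_density_edge_count(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(size=(16, 16))
        m = 0.5 * (m + m.T)
        net = binarize(m, "proportional", 0.3)
        assert net.n_edges == math.ceil(0.3 * 120)  # 36

    def test_uniform_matrix_high_threshold_empty(self):
        m = np.full((8, 8), 0.4)
        np.fill_diagonal(m, 1.0)
        net = binarize(m, "absolute", 0.5)
        assert net.n_edges == 0

    def test_proportional_tie_break_is_row_col_order(self):
        m = np.full((5, 5), 0.4)
        np.fill_diagonal(m, 1.0)
        net = binarize(m, "proportional", 0.3)  # ceil(0.3*10) = 3 edges
        assert net.edge_list() == [(0, 1), (0, 2), (0, 3)]

    def test_proportional_edge_count_monotone_in_density(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(size=(10, 10))
        m = 0.5 * (m + m.T)
        counts = [binarize(m, "proportional", d).n_edges for d in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_diagonal_never_an_edge(self):
        m = np.ones((6, 6))
        net = binarize(m, "absolute", 0.1)
        assert np.diag(net.adjacency).sum() == 0

    def test_invalid_param_rejected(self):
        with pytest.raises(ConnectivityError):
            binarize(np.eye(4), "absolute", 1.5)

    def test_network_validation(self):
        with pytest.raises(ConnectivityError):
            BinaryNetwork(adjacency=np.array([[0, 1], [0, 0]]))  # asymmetric
        with pytest.raises(ConnectivityError):
            BinaryNetwork(adjacency=np.array([[1, 1], [1, 0]]))  # non-hollow
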