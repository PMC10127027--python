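"""Spectral coherence estimation and functional-network construction.

Functional connectivity between two LFP channels x and y is the magnitude-
squared coherence

    Coh_xy(f) = |p_xy(f)|^2 / (p_x(f) * p_y(f)),

with the cross-spectrum estimated by averaging Hann-tapered windowed FFTs

    p_xy(f) = (1/n) * sum_i  x_i(f) * conj(y_i(f))

over the n overlapping windows of the trial, and the auto-spectra by the same
average with y = x.  Per-band connection weights are the mean of Coh over the
FFT bins whose centre frequency falls in the band (closed interval).  The
resulting symmetric, unit-diagonal coherence matrix is thresholded into a
binary adjacency — the functional network whose topology is quantified in
:mod:`hippoconn.netmetrics`.

Coherence lies in [0, 1] by the Cauchy-Schwarz inequality applied to the
window-averaged cross products; no clamping is performed anywhere, so an
out-of-range value would indicate a bug, not a numerical nicety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .preprocess import BandDefinition, SOISegment


class DegenerateEstimateError(ValueError):
    """Fewer than two averaging windows: coherence would be identically 1."""


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralParams:
    """Welch settings: window length in seconds and fractional overlap."""

    window_s: float = 1.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConnectivityError("window_s must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ConnectivityError("overlap must lie in [0, 1)")


@dataclass
class SpectralEstimate:
    """Averaged auto- and cross-spectra of one channel pair."""

    frequencies: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray
    p_xy: np.ndarray  # complex
    n_windows: int


@dataclass
class CoherenceSpectrum:
    frequencies: np.ndarray
    coherence: np.ndarray
    low_power: np.ndarray  # bins zeroed because an auto-spectrum was ~0


@dataclass
class BandCoherenceMatrix:
    """Symmetric, unit-diagonal channels x channels band-coherence matrix."""

    band: BandDefinition
    matrix: np.ndarray
    trial_id: int = -1
    phase: str = ""
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def _window_starts(n_samples: int, nperseg: int, hop: int) -> range:
    if n_samples < nperseg:
        return range(0)
    return range(0, n_samples - nperseg + 1, hop)


def _windowed_fft(
    x: np.ndarray, fs: float, params: SpectralParams
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered sliding-window rFFTs, shape (n_windows, n_bins).

    Scaled so that |X|^2 averaged over windows is a one-sided power density
    up to the constant one-sided doubling (which cancels in coherence).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConnectivityError("expected a 1-D signal")
    nperseg = int(round(params.window_s * fs))
    if nperseg < 2:
        raise ConnectivityError("window too short for this sampling rate")
    hop = max(1, int(round(nperseg * (1.0 - params.overlap))))
    starts = _window_starts(x.shape[0], nperseg, hop)
    n_windows = len(starts)
    if n_windows < 2:
        raise DegenerateEstimateError(
            f"only {n_windows} full window(s) of {params.window_s} s fit; "
            "coherence needs at least 2 averaging windows"
        )
    taper = _sig.get_window("hann", nperseg)
    scale = 1.0 / math.sqrt(fs * (taper**2).sum())
    segs = np.stack([x[s : s + nperseg] for s in starts])
    X = np.fft.rfft(segs * taper, axis=1) * scale
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, X


def welch_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Window-averaged auto/cross spectra of a channel pair.

    Refuses to produce a single-window estimate (its coherence is identically
    one regardless of the data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConnectivityError("signals must have equal length")
    params = SpectralParams(window_s=window_s, overlap=overlap)
    freqs, X = _windowed_fft(x, fs, params)
    _, Y = _windowed_fft(y, fs, params)
    p_x = (X * X.conj()).real.mean(axis=0)
    p_y = (Y * Y.conj()).real.mean(axis=0)
    p_xy = (X * Y.conj()).mean(axis=0)
    return SpectralEstimate(freqs, p_x, p_y, p_xy, X.shape[0])


_POWER_FLOOR = 1e-300


def coherence(est: SpectralEstimate) -> CoherenceSpectrum:
    """Magnitude-squared coherence of an averaged spectral estimate.

    Bins where either auto-spectrum has (numerically) no power are set to 0
    and flagged in ``low_power`` rather than returned as 0/0.
    """
    if est.n_windows < 2:
        raise DegenerateEstimateError("estimate has fewer than 2 windows")
    denom = est.p_x * est.p_y
    low = denom <= _POWER_FLOOR
    coh = np.zeros_like(denom)
    np.divide(np.abs(est.p_xy) ** 2, denom, out=coh, where=~low)
    return CoherenceSpectrum(est.frequencies, coh, low)


def _channel_ffts(
    samples: np.ndarray, fs: float, params: SpectralParams
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed FFTs for every channel at once: (n_windows, n_channels, n_bins)."""
    cols = []
    freqs = None
    for c in range(samples.shape[1]):
        freqs, X = _windowed_fft(samples[:, c], fs, params)
        cols.append(X)
    return freqs, np.stack(cols, axis=1)


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    return np.flatnonzero((freqs >= band.lo_hz) & (freqs <= band.hi_hz))


def band_coherence_matrices(
    segment: SOISegment,
    bands: Sequence[BandDefinition],
    params: SpectralParams = SpectralParams(),
) -> list[BandCoherenceMatrix]:
    """Per-band coherence matrices of one trial, sharing one FFT pass.

    Numerically identical (to within summation-order rounding) to calling
    :func:`welch_spectra` + :func:`coherence` on every channel pair.
    """
    fs = segment.sampling_rate_hz
    freqs, X = _channel_ffts(segment.samples, fs, params)
    n_ch = X.shape[1]
    bins_per_band = []
    for band in bands:
        bins = _band_bins(freqs, band)
        if bins.size == 0:
            raise ConnectivityError(
                f"band {band.name!r} contains no FFT bin at a resolution of "
                f"{freqs[1] - freqs[0]:.3g} Hz; use a longer window"
            )
        bins_per_band.append(bins)
    used = np.unique(np.concatenate(bins_per_band))
    Xb = X[:, :, used]
    # full cross-spectral tensor at the needed bins, averaged over windows
    p = np.einsum("wif,wjf->ijf", Xb, Xb.conj()) / X.shape[0]
    auto = np.einsum("iif->if", p).real
    denom = auto[:, None, :] * auto[None, :, :]
    low = denom <= _POWER_FLOOR
    coh = np.zeros_like(denom)
    np.divide(np.abs(p) ** 2, denom, out=coh, where=~low)
    pos = {b: k for k, b in enumerate(used)}
    out = []
    for band, bins in zip(bands, bins_per_band):
        sel = [pos[b] for b in bins]
        mat = coh[:, :, sel].mean(axis=2)
        mat = 0.5 * (mat + mat.T)  # exact symmetry against rounding asymmetry
        np.fill_diagonal(mat, 1.0)
        out.append(
            BandCoherenceMatrix(
                band=band,
                matrix=mat,
                trial_id=segment.trial_id,
                phase=segment.phase,
                channel_labels=list(segment.channel_labels),
            )
        )
    return out


def band_coherence_matrix(
    segment: SOISegment,
    band: BandDefinition,
    params: SpectralParams = SpectralParams(),
) -> BandCoherenceMatrix:
    """Band-averaged coherence between every pair of good channels."""
    return band_coherence_matrices(segment, [band], params)[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted functional network (symmetric hollow 0/1)."""

    adjacency: np.ndarray
    band: str = ""
    trial_id: int = -1
    phase: str = ""
    threshold_spec: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectivityError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ConnectivityError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ConnectivityError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ConnectivityError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbor_edge_count(self, i: int) -> int:
        """Number of edges among the neighbours of node ``i``."""
        nbr = np.flatnonzero(self.adjacency[i])
        return int(self.adjacency[np.ix_(nbr, nbr)].sum()) // 2

    def distances(self) -> np.ndarray:
        """All-pairs shortest-path lengths (np.inf where disconnected)."""
        return _csgraph_shortest_path(
            csr_matrix(self.adjacency), method="D", unweighted=True, directed=False
        )

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


def binarize(
    matrix: BandCoherenceMatrix | np.ndarray,
    method: Literal["absolute", "proportional"] = "absolute",
    param: float = 0.3,
) -> BinaryNetwork:
    """Threshold a coherence matrix into a binary functional network.

    ``absolute`` keeps edges whose weight exceeds ``param``; ``proportional``
    keeps the ``ceil(param * M(M-1)/2)`` strongest off-diagonal pairs, breaking
    ties by ascending (row, col) index.  The diagonal is never an edge.
    """
    if not (0.0 <= param <= 1.0):
        raise ConnectivityError("binarization parameter must lie in [0, 1]")
    if isinstance(matrix, BandCoherenceMatrix):
        vals = matrix.matrix
        meta = dict(band=matrix.band.name, trial_id=matrix.trial_id, phase=matrix.phase)
    else:
        vals = np.asarray(matrix, dtype=float)
        meta = {}
    m = vals.shape[0]
    adj = np.zeros((m, m), dtype=np.int8)
    iu, ju = np.triu_indices(m, k=1)
    if method == "absolute":
        keep = vals[iu, ju] > param
        adj[iu[keep], ju[keep]] = 1
    elif method == "proportional":
        n_pairs = iu.size
        n_keep = math.ceil(param * n_pairs)
        order = sorted(range(n_pairs), key=lambda k: (-vals[iu[k], ju[k]], iu[k], ju[k]))
        sel = order[:n_keep]
        adj[iu[sel], ju[sel]] = 1
    else:
        raise ConnectivityError(f"unknown binarization method {method!r}")
    adj = adj | adj.T
    return BinaryNetwork(adjacency=adj, threshold_spec=f"{method}:{param}", **meta)
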