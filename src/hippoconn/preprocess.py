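"""LFP preprocessing: channel screening, trial segmentation and band filtering.

The recording model is a dense ``samples x channels`` float matrix at a fixed
sampling rate (2 kHz for the chronic hippocampal array this package targets),
already low-passed by the acquisition chain.  All filters here are zero-phase
Butterworth (forward-backward), so band decomposition does not shift event
timing relative to the behavioral log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal


class PreprocessError(ValueError):
    """Raised for invalid filter settings, events or channel screens."""


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo_hz, hi_hz]``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo_hz < self.hi_hz):
            raise PreprocessError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz}]"
            )


#: The five canonical hippocampal LFP rhythms analysed by this package.  The
#: 45-55 Hz gap between the gamma bands is deliberate (mains avoidance) and is
#: never merged.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 5.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("slow_gamma", 31.0, 45.0),
    BandDefinition("fast_gamma", 55.0, 80.0),
)


@dataclass
class LFPRecording:
    """Multichannel LFP: ``samples`` is (n_samples, n_channels).

    ``channel_mask`` is True for channels judged reliable; freshly constructed
    recordings default to all-good.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str] = field(default_factory=list)
    channel_mask: np.ndarray | None = None
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise PreprocessError("samples must be a 2-D (time x channels) array")
        if self.sampling_rate_hz <= 0:
            raise PreprocessError("sampling_rate_hz must be positive")
        n_ch = self.samples.shape[1]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n_ch)]
        if len(self.channel_labels) != n_ch:
            raise PreprocessError("channel_labels length must match channel count")
        if self.channel_mask is None:
            self.channel_mask = np.ones(n_ch, dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        if self.channel_mask.shape != (n_ch,):
            raise PreprocessError("channel_mask length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class TrialEvent:
    """Gate-delimited trial window used to cut signals of interest."""

    trial_id: int
    phase: str
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise PreprocessError(
                f"trial {self.trial_id}: t_end_s must exceed t_start_s"
            )


@dataclass
class SOISegment:
    """Signal of interest: one trial's LFP window restricted to good channels."""

    trial_id: int
    phase: str
    samples: np.ndarray  # (window samples, good channels)
    t_start_s: float
    t_end_s: float
    sampling_rate_hz: float
    channel_labels: list[str]


def _apply_sos(recording: LFPRecording, sos: np.ndarray) -> LFPRecording:
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=0)
    return replace(recording, samples=np.ascontiguousarray(filtered))


def lowpass_filter(
    recording: LFPRecording, cutoff_hz: float = 250.0, order: int = 4
) -> LFPRecording:
    """Zero-phase Butterworth low-pass, applied per channel.

    Mirrors the acquisition-side 0-250 Hz anti-alias filter so that synthetic
    and re-exported recordings pass through the same transfer function.
    """
    nyq = recording.sampling_rate_hz / 2.0
    if not (0.0 < cutoff_hz < nyq):
        raise PreprocessError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=recording.sampling_rate_hz, output="sos")
    return _apply_sos(recording, sos)


def bandpass_filter(
    recording: LFPRecording, band: BandDefinition, order: int = 4
) -> LFPRecording:
    """Zero-phase Butterworth band-pass onto ``band``; length preserved."""
    nyq = recording.sampling_rate_hz / 2.0
    if not (0.0 < band.lo_hz < band.hi_hz < nyq):
        raise PreprocessError(
            f"band {band.name!r} [{band.lo_hz}, {band.hi_hz}] Hz outside (0, {nyq}) Hz"
        )
    sos = signal.butter(
        order,
        (band.lo_hz, band.hi_hz),
        btype="bandpass",
        fs=recording.sampling_rate_hz,
        output="sos",
    )
    return _apply_sos(recording, sos)


@dataclass(frozen=True)
class BadChannelCriteria:
    """Objective screen for unreliable channels.

    A channel is rejected when it is flatlined (variance below
    ``variance_floor_ratio`` times the median channel variance), saturated
    (more than ``saturation_fraction`` of samples pinned at the channel's
    min/max rail), or line-dominated (more than ``line_power_ratio`` of its
    power within ``line_halfwidth_hz`` of ``line_hz``).
    """

    variance_floor_ratio: float = 1e-3
    saturation_fraction: float = 0.01
    line_hz: float = 50.0
    line_halfwidth_hz: float = 1.0
    line_power_ratio: float = 0.5


def detect_bad_channels(
    recording: LFPRecording, criteria: BadChannelCriteria = BadChannelCriteria()
) -> np.ndarray:
    """Return a boolean good-channel mask (True = keep); deterministic.

    Raises if every channel is rejected — there is nothing left to analyse.
    """
    x = recording.samples
    if x.size == 0:
        raise PreprocessError("empty recording")
    variances = x.var(axis=0)
    var_floor = criteria.variance_floor_ratio * np.median(variances)
    flat = variances <= var_floor

    rail_lo = x.min(axis=0)
    rail_hi = x.max(axis=0)
    span = rail_hi - rail_lo
    tol = np.where(span > 0, span * 1e-9, np.inf)
    at_rail = (np.abs(x - rail_lo) <= tol) | (np.abs(x - rail_hi) <= tol)
    saturated = at_rail.mean(axis=0) > criteria.saturation_fraction

    nperseg = min(x.shape[0], 4096)
    freqs, psd = signal.welch(x, fs=recording.sampling_rate_hz, nperseg=nperseg, axis=0)
    in_line = np.abs(freqs - criteria.line_hz) <= criteria.line_halfwidth_hz
    total = psd.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        line_ratio = np.where(total > 0, psd[in_line].sum(axis=0) / total, 0.0)
    line_dominated = line_ratio > criteria.line_power_ratio

    good = ~(flat | saturated | line_dominated)
    if not good.any():
        raise PreprocessError("all channels rejected by quality screen")
    return good


def segment_soi(
    recording: LFPRecording, events: Sequence[TrialEvent]
) -> list[SOISegment]:
    """Cut one signal-of-interest window per trial, good channels only.

    Windows are half-open ``[t_start, t_end)`` in samples; events must be
    non-overlapping and lie inside the recording.
    """
    fs = recording.sampling_rate_hz
    ordered = sorted(events, key=lambda e: e.t_start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.t_start_s < prev.t_end_s - 0.5 / fs:
            raise PreprocessError(
                f"trials {prev.trial_id} and {nxt.trial_id} overlap"
            )
    good = np.flatnonzero(recording.channel_mask)
    labels = [recording.channel_labels[i] for i in good]
    segments: list[SOISegment] = []
    for ev in events:
        i0 = int(round(ev.t_start_s * fs))
        i1 = int(round(ev.t_end_s * fs))
        if i0 < 0 or i1 > recording.n_samples:
            raise PreprocessError(
                f"trial {ev.trial_id}: window [{ev.t_start_s}, {ev.t_end_s}] s "
                "falls outside the recording"
            )
        segments.append(
            SOISegment(
                trial_id=ev.trial_id,
                phase=ev.phase,
                samples=recording.samples[i0:i1, good].copy(),
                t_start_s=ev.t_start_s,
                t_end_s=ev.t_end_s,
                sampling_rate_hz=fs,
                channel_labels=labels,
            )
        )
    return segments
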