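"""Synthetic LFP sessions and detour-maze behavior with planted structure.

The generator is the test bed for the whole pipeline: it plants a known,
phase-dependent coupling structure into a multichannel LFP session and a
known duration/path-length elongation into the behavioral session, so every
downstream estimate can be checked against ground truth.

Signal model (per trial, per channel i):

    x_i(t) = sum_b [ sqrt(c_{b,phase}) * s_b(t) + sqrt(1 - c_{b,phase}) * e_{b,i}(t) ]
             + pink noise + white noise + line component,

where s_b is a band-limited unit-variance Gaussian source shared by the
channels of a coupling group, e_{b,i} is an independent band-limited private
source, and c in [0, 1] is the planted coupling strength.  In-band coherence
between two channels of a group is then approximately c^2 (shrunk slightly by
broadband noise), so phase differences in c translate directly into the
band- and phase-specific connectivity patterns the analysis must recover:
depressed delta/theta coupling and elevated gamma coupling during path
adjustment, with beta flat across phases.

Band-limited sources are synthesized by drawing i.i.d. complex Gaussian rFFT
coefficients on the in-band bins only (the distribution of brick-wall
band-pass-filtered white Gaussian noise).  Sinusoidal sources are
deliberately avoided: a deterministic narrowband tone makes the coherence
estimator degenerate for every estimator setting.

Behavioral model: acquisition trials follow the preferred shortest maze path
with waypoint jitter; adjustment trials are goal-absorbing random walks on
the blocked maze (stochastically longer); recovery trials follow a fixed new
shortest path of the same graph length as the preferred one.  Duration is
path length / speed plus a small gate-latency noise.

All randomness derives from an explicit integer seed through fixed-offset
sub-streams, so identical (config, seed) pairs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import fft as sfft

from .behavior import TrialRecord
from .preprocess import DEFAULT_BANDS, BandDefinition, LFPRecording, TrialEvent

PHASES: tuple[str, str, str] = ("acquisition", "adjustment", "recovery")


class InvalidConfigError(ValueError):
    pass


class InvalidMazeError(ValueError):
    pass


@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling of one band in one phase.

    ``strength`` is the fraction of each group channel's in-band variance
    carried by the shared source; ``channel_groups`` lists the channel index
    groups sharing a source (None = one group spanning all channels).
    """

    strength: float
    channel_groups: tuple[tuple[int, ...], ...] | None = None


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 0.5
    pink_sd: float = 0.5
    line_hz: float = 50.0
    line_sd: float = 0.2


@dataclass(frozen=True)
class MazeSpec:
    """Rectangular grid maze; nodes are (row, col), pathlets are grid edges."""

    shape: tuple[int, int] = (4, 4)
    start: tuple[int, int] = (0, 0)
    goal: tuple[int, int] = (3, 3)
    blocked_edge: tuple[tuple[int, int], tuple[int, int]] | None = None  # None = last preferred edge


def default_coupling_plan() -> dict[str, dict[str, CouplingSpec]]:
    """Phase -> band -> coupling reproducing the detour-task connectivity pattern.

    Delta/theta coupling drops during adjustment, slow/fast gamma rises,
    beta stays flat.
    """
    high, low, flat = 0.8, 0.2, 0.7
    return {
        "acquisition": {
            "delta": CouplingSpec(high),
            "theta": CouplingSpec(high),
            "beta": CouplingSpec(flat),
            "slow_gamma": CouplingSpec(low),
            "fast_gamma": CouplingSpec(low),
        },
        "adjustment": {
            "delta": CouplingSpec(low),
            "theta": CouplingSpec(low),
            "beta": CouplingSpec(flat),
            "slow_gamma": CouplingSpec(high),
            "fast_gamma": CouplingSpec(high),
        },
        "recovery": {
            "delta": CouplingSpec(high),
            "theta": CouplingSpec(high),
            "beta": CouplingSpec(flat),
            "slow_gamma": CouplingSpec(low),
            "fast_gamma": CouplingSpec(low),
        },
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session."""

    n_channels: int = 16
    sampling_rate_hz: float = 2000.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    coupling_plan: dict[str, dict[str, CouplingSpec]] = field(
        default_factory=default_coupling_plan
    )
    noise: NoiseSpec = NoiseSpec()
    trials_per_phase: dict[str, int] = field(
        default_factory=lambda: {p: 20 for p in PHASES}
    )
    trial_duration_s: tuple[float, float] = (8.0, 12.0)
    gap_s: float = 1.0
    maze: MazeSpec = MazeSpec()
    speed: float = 0.5  # arena units / s
    camera_rate_hz: float = 30.0
    waypoint_jitter_sd: float = 0.05
    timing_noise_sd: float = 0.05
    trials_per_day: int = 10
    max_walk_steps: int = 400

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.n_channels < 2:
            errors.append("n_channels must be >= 2")
        if self.sampling_rate_hz <= 0:
            errors.append("sampling_rate_hz must be positive")
        nyq = self.sampling_rate_hz / 2.0
        for band in self.bands:
            if not (0.0 < band.lo_hz < band.hi_hz < nyq):
                errors.append(
                    f"band {band.name!r} [{band.lo_hz}, {band.hi_hz}] Hz "
                    f"outside (0, {nyq}) Hz"
                )
        for phase, per_band in self.coupling_plan.items():
            if phase not in PHASES:
                errors.append(f"unknown phase {phase!r} in coupling plan")
            band_names = {b.name for b in self.bands}
            for name, spec in per_band.items():
                if name not in band_names:
                    errors.append(f"coupling plan names unknown band {name!r}")
                if not (0.0 <= spec.strength <= 1.0):
                    errors.append(
                        f"coupling strength for {phase}/{name} must lie in [0, 1]"
                    )
                if spec.channel_groups is not None:
                    for grp in spec.channel_groups:
                        if any(not (0 <= ch < self.n_channels) for ch in grp):
                            errors.append(
                                f"channel group {grp} for {phase}/{name} "
                                f"outside 0..{self.n_channels - 1}"
                            )
        for phase in PHASES:
            if self.trials_per_phase.get(phase, 0) < 1:
                errors.append(f"trials_per_phase[{phase!r}] must be >= 1")
        lo, hi = self.trial_duration_s
        if not (0 < lo <= hi):
            errors.append("trial_duration_s must be a positive (lo, hi) range")
        if self.speed <= 0:
            errors.append("speed must be positive")
        if self.camera_rate_hz <= 0:
            errors.append("camera_rate_hz must be positive")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise InvalidConfigError("; ".join(errors))


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery tests.

    ``coupling[phase][band]`` is the CouplingSpec actually used;
    ``expected_coherence[phase][band]`` is the noise-free in-band coherence
    c^2 implied between two channels of the same group.
    """

    coupling: dict[str, dict[str, CouplingSpec]]
    expected_coherence: dict[str, dict[str, float]]
    band_names: tuple[str, ...]


def _resolve_spec(
    config: SimulationConfig, phase: str, band: BandDefinition
) -> CouplingSpec:
    spec = config.coupling_plan.get(phase, {}).get(band.name)
    if spec is None:
        spec = CouplingSpec(0.0)
    return spec


def build_planted_truth(config: SimulationConfig) -> PlantedTruth:
    coupling = {
        phase: {band.name: _resolve_spec(config, phase, band) for band in config.bands}
        for phase in PHASES
    }
    expected = {
        phase: {name: spec.strength**2 for name, spec in per_band.items()}
        for phase, per_band in coupling.items()
    }
    return PlantedTruth(
        coupling=coupling,
        expected_coherence=expected,
        band_names=tuple(b.name for b in config.bands),
    )


def planted_ordering(truth: PlantedTruth, band: str | BandDefinition) -> list[set[str]]:
    """Phases grouped by expected in-band connectivity, ascending.

    Phases with equal planted coupling share a set; a single set containing
    all phases means the band is flat (no planted ordering).
    """
    name = band.name if isinstance(band, BandDefinition) else band
    if name not in truth.band_names:
        raise InvalidConfigError(f"band {name!r} not in the simulated band table")
    levels: dict[float, set[str]] = {}
    for phase in PHASES:
        value = truth.expected_coherence[phase][name]
        key = round(value, 12)
        levels.setdefault(key, set()).add(phase)
    return [levels[k] for k in sorted(levels)]


# ---------------------------------------------------------------------------
# signal synthesis


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz.

    Drawn directly in the frequency domain: i.i.d. complex Gaussian rFFT
    coefficients on the in-band bins, zero elsewhere (the distribution of
    brick-wall band-pass-filtered white Gaussian noise).  Synthesized on an
    FFT-friendly grid of at least ``n`` points and truncated.
    """
    m = int(sfft.next_fast_len(n))
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    bins = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if bins.size == 0:
        raise InvalidConfigError(f"band [{lo}, {hi}] Hz contains no FFT bin at n={n}")
    z = np.zeros(freqs.size, dtype=complex)
    z[bins] = rng.standard_normal(bins.size) + 1j * rng.standard_normal(bins.size)
    s = sfft.irfft(z, m)[:n]
    return s / s.std()


def pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with total standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    m = int(sfft.next_fast_len(n))
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    s = sfft.irfft(z * shape, m)[:n]
    return s * (sd / s.std())


def simulate_lfp_session(
    config: SimulationConfig, seed: int
) -> tuple[LFPRecording, list[TrialEvent], PlantedTruth]:
    """Synthesize one session's multichannel LFP with planted coupling.

    Trials run in phase order (acquisition, adjustment, recovery) separated
    by noise-only gaps; the returned events delimit each trial's signal of
    interest.
    """
    config.require_valid()
    fs = config.sampling_rate_hz
    truth = build_planted_truth(config)

    rng_dur = _rng(seed, 1)
    lo, hi = config.trial_duration_s
    trial_meta: list[tuple[int, str, float]] = []  # (trial_id, phase, duration)
    tid = 0
    for phase in PHASES:
        for _ in range(config.trials_per_phase[phase]):
            trial_meta.append((tid, phase, float(rng_dur.uniform(lo, hi))))
            tid += 1

    gap_n = int(round(config.gap_s * fs))
    trial_ns = [int(round(d * fs)) for _, _, d in trial_meta]
    total_n = gap_n + sum(n + gap_n for n in trial_ns)
    samples = np.zeros((total_n, config.n_channels))

    # session-wide background noise, one sub-stream per channel
    noise = config.noise
    t_grid = np.arange(total_n) / fs
    for ch in range(config.n_channels):
        rng_n = _rng(seed, 2, ch)
        x = noise.white_sd * rng_n.standard_normal(total_n)
        x += pink_noise(rng_n, total_n, fs, noise.pink_sd)
        if noise.line_sd > 0:
            phase_off = rng_n.uniform(0, 2 * math.pi)
            x += noise.line_sd * math.sqrt(2.0) * np.sin(
                2 * math.pi * noise.line_hz * t_grid + phase_off
            )
        samples[:, ch] = x

    events: list[TrialEvent] = []
    cursor = gap_n
    for (trial_id, phase, duration), n in zip(trial_meta, trial_ns):
        rng_t = _rng(seed, 3, trial_id)
        for band in config.bands:
            spec = _resolve_spec(config, phase, band)
            c = spec.strength
            groups = spec.channel_groups
            if groups is None:
                groups = (tuple(range(config.n_channels)),)
            grouped = set()
            for grp in groups:
                shared = band_limited_noise(rng_t, n, fs, band.lo_hz, band.hi_hz)
                for ch in grp:
                    private = band_limited_noise(rng_t, n, fs, band.lo_hz, band.hi_hz)
                    samples[cursor : cursor + n, ch] += (
                        math.sqrt(c) * shared + math.sqrt(1.0 - c) * private
                    )
                    grouped.add(ch)
            for ch in range(config.n_channels):
                if ch not in grouped:
                    samples[cursor : cursor + n, ch] += band_limited_noise(
                        rng_t, n, fs, band.lo_hz, band.hi_hz
                    )
        events.append(
            TrialEvent(
                trial_id=trial_id,
                phase=phase,
                t_start_s=cursor / fs,
                t_end_s=(cursor + n) / fs,
            )
        )
        cursor += n + gap_n

    recording = LFPRecording(
        samples=samples,
        sampling_rate_hz=fs,
        channel_labels=[f"ch{i:02d}" for i in range(config.n_channels)],
    )
    return recording, events, truth


# ---------------------------------------------------------------------------
# behavior synthesis


def _edge_id(a: tuple[int, int], b: tuple[int, int]) -> tuple:
    return (a, b) if a <= b else (b, a)


def _maze_graphs(maze: MazeSpec) -> tuple[nx.Graph, nx.Graph, list, list]:
    """Full and blocked maze graphs plus preferred and recovery node paths."""
    g = nx.grid_2d_graph(*maze.shape)
    if maze.start not in g or maze.goal not in g:
        raise InvalidMazeError("start or goal outside the maze grid")
    preferred = nx.shortest_path(g, maze.start, maze.goal)
    blocked_edge = maze.blocked_edge
    if blocked_edge is None:
        blocked_edge = (preferred[-2], preferred[-1])
    if not g.has_edge(*blocked_edge):
        raise InvalidMazeError(f"blocked edge {blocked_edge} not in the maze")
    g_blocked = g.copy()
    g_blocked.remove_edge(*blocked_edge)
    if not nx.has_path(g_blocked, maze.start, maze.goal):
        raise InvalidMazeError("goal unreachable after blocking the preferred edge")
    recovery = nx.shortest_path(g_blocked, maze.start, maze.goal)
    return g, g_blocked, preferred, recovery


def _random_walk(
    rng: np.random.Generator, g: nx.Graph, start, goal, max_steps: int
) -> list:
    """Uniform random walk absorbed at the goal, shortest-path completed at the cap."""
    node = start
    path = [node]
    for _ in range(max_steps):
        if node == goal:
            return path
        nbrs = sorted(g.neighbors(node))
        node = nbrs[rng.integers(len(nbrs))]
        path.append(node)
    if node != goal:
        path.extend(nx.shortest_path(g, node, goal)[1:])
    return path


def _trajectory(
    rng: np.random.Generator,
    waypoints: list,
    t_start: float,
    speed: float,
    camera_rate_hz: float,
    jitter_sd: float,
) -> tuple[np.ndarray, float]:
    """Camera-rate samples along the jittered waypoint polyline.

    Returns the (t, x, y) array and the traversal time of the recorded
    track (its arc length divided by the walking speed), so that trial
    duration and path length are measurements of the same walk.
    """
    pts = np.asarray(waypoints, dtype=float)
    pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total_len = float(cum[-1])
    n_pts = max(2, int(math.floor(total_len / speed * camera_rate_hz)) + 1)
    t_rel = np.arange(n_pts) / camera_rate_hz
    d = np.minimum(t_rel * speed, total_len)
    x = np.interp(d, cum, pts[:, 0])
    y = np.interp(d, cum, pts[:, 1])
    track = np.column_stack([t_start + t_rel, x, y])
    track_len = float(np.sqrt((np.diff(track[:, 1:], axis=0) ** 2).sum(axis=1)).sum())
    return track, track_len / speed


def simulate_behavior_session(
    config: SimulationConfig, seed: int
) -> list[TrialRecord]:
    """Synthesize one session of maze trials with the three-phase structure."""
    config.require_valid()
    maze = config.maze
    _, g_blocked, preferred, recovery = _maze_graphs(maze)

    records: list[TrialRecord] = []
    t_cursor = 0.0
    tid = 0
    for phase in PHASES:
        for _ in range(config.trials_per_phase[phase]):
            rng_t = _rng(seed, 4, tid)
            if phase == "acquisition":
                waypoints = preferred
            elif phase == "adjustment":
                waypoints = _random_walk(
                    rng_t, g_blocked, maze.start, maze.goal, config.max_walk_steps
                )
            else:
                waypoints = recovery
            traj, travel_t = _trajectory(
                rng_t,
                waypoints,
                t_cursor,
                config.speed,
                config.camera_rate_hz,
                config.waypoint_jitter_sd,
            )
            latency = abs(rng_t.normal(0.0, config.timing_noise_sd))
            duration = travel_t + latency
            signature = tuple(
                _edge_id(a, b) for a, b in zip(waypoints, waypoints[1:])
            )
            records.append(
                TrialRecord(
                    trial_id=tid,
                    t_start_s=t_cursor,
                    t_goal_s=t_cursor + duration,
                    trajectory=traj,
                    path_signature=signature,
                    phase=phase,
                    correct=waypoints[-1] == maze.goal,
                    day_index=tid // config.trials_per_day,
                )
            )
            t_cursor += duration + 5.0  # inter-trial interval back at the start box
            tid += 1
    return records
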