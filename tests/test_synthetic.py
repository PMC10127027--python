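"""Synthetic LFP and behavior generation: determinism and planted structure."""

import numpy as np
import pytest
from scipy import signal as spsig

from hippoconn.behavior import compute_duration, compute_path_length
from hippoconn.connectivity import band_coherence_matrix, coherence, welch_spectra
from hippoconn.preprocess import BandDefinition, DEFAULT_BANDS, segment_soi
from hippoconn.stats import ranksum
from hippoconn.synthetic import (
    CouplingSpec,
    InvalidConfigError,
    InvalidMazeError,
    MazeSpec,
    NoiseSpec,
    PHASES,
    SimulationConfig,
    band_limited_noise,
    build_planted_truth,
    pink_noise,
    planted_ordering,
    simulate_behavior_session,
    simulate_lfp_session,
)

FS = 2000.0


class TestBandLimitedSources:
    @pytest.mark.parametrize("band", DEFAULT_BANDS, ids=lambda b: b.name)
    def test_spectral_confinement(self, band):
        rng = np.random.default_rng(0)
        x = band_limited_noise(rng, 12345, FS, band.lo_hz, band.hi_hz)
        f, p = spsig.periodogram(x, fs=FS)
        inside = (f >= band.lo_hz - 1.0) & (f <= band.hi_hz + 1.0)
        assert p[inside].sum() >= 0.95 * p.sum()

    def test_unit_variance(self):
        rng = np.random.default_rng(1)
        x = band_limited_noise(rng, 10000, FS, 5, 12)
        assert x.std() == pytest.approx(1.0)

    def test_pink_noise_amplitude(self):
        rng = np.random.default_rng(2)
        x = pink_noise(rng, 50000, FS, 0.7)
        assert x.std() == pytest.approx(0.7)

    def test_shared_source_plus_noise_recovers_closed_form_coherence(self):
        # x = s + n1, y = s + n2 with in-band source density P_s and white
        # noise density P_n: band coherence -> (P_s / (P_s + P_n))^2
        rng = np.random.default_rng(3)
        n = 120000  # 60 s -> 119 half-overlapping 1 s windows
        sigma = 2.0
        s = band_limited_noise(rng, n, FS, 5.0, 12.0)
        x = s + sigma * rng.standard_normal(n)
        y = s + sigma * rng.standard_normal(n)
        coh = coherence(welch_spectra(x, y, FS))
        bins = (coh.frequencies >= 6) & (coh.frequencies <= 11)  # interior bins
        p_s = 1.0 / 7.0  # unit power over the 7 Hz band
        p_n = sigma**2 / (FS / 2)
        expected = (p_s / (p_s + p_n)) ** 2
        assert coh.coherence[bins].mean() == pytest.approx(expected, abs=0.02)


class TestSimulateLFP:
    def test_same_seed_bit_identical(self, tiny_sim_config):
        r1, e1, _ = simulate_lfp_session(tiny_sim_config, 11)
        r2, e2, _ = simulate_lfp_session(tiny_sim_config, 11)
        assert np.array_equal(r1.samples, r2.samples)
        assert e1 == e2

    def test_different_seed_differs(self, tiny_sim_config):
        r1, _, _ = simulate_lfp_session(tiny_sim_config, 11)
        r2, _, _ = simulate_lfp_session(tiny_sim_config, 12)
        assert not np.array_equal(r1.samples, r2.samples)

    def test_band_outside_nyquist_rejected(self, tiny_sim_config):
        tiny_sim_config.bands = (BandDefinition("bad", 900.0, 1500.0),)
        tiny_sim_config.coupling_plan = {}
        with pytest.raises(InvalidConfigError):
            simulate_lfp_session(tiny_sim_config, 0)

    def test_fully_coupled_pair_near_unit_theta_coherence(self):
        theta = BandDefinition("theta", 5.0, 12.0)
        cfg = SimulationConfig(
            n_channels=2,
            bands=(theta,),
            coupling_plan={p: {"theta": CouplingSpec(1.0)} for p in PHASES},
            noise=NoiseSpec(white_sd=0.0, pink_sd=0.0, line_sd=0.0),
            trials_per_phase={p: 1 for p in PHASES},
            trial_duration_s=(8.0, 8.0),
        )
        rec, events, _ = simulate_lfp_session(cfg, 5)
        seg = segment_soi(rec, events[:1])[0]
        mat = band_coherence_matrix(seg, theta)
        assert mat.matrix[0, 1] > 0.99

    def test_events_delimit_trials_within_recording(self, tiny_sim_config):
        rec, events, _ = simulate_lfp_session(tiny_sim_config, 6)
        assert len(events) == 6
        assert all(e.t_end_s <= rec.duration_s for e in events)
        segs = segment_soi(rec, events)
        for e, s in zip(events, segs):
            assert s.samples.shape[0] == round((e.t_end_s - e.t_start_s) * FS)


class TestPlantedTruth:
    def test_theta_ordering_low_in_adjustment(self):
        truth = build_planted_truth(SimulationConfig())
        assert planted_ordering(truth, "theta") == [
            {"adjustment"},
            {"acquisition", "recovery"},
        ]

    def test_slow_gamma_ordering_reversed(self):
        truth = build_planted_truth(SimulationConfig())
        assert planted_ordering(truth, "slow_gamma") == [
            {"acquisition", "recovery"},
            {"adjustment"},
        ]

    def test_flat_band_single_group(self):
        truth = build_planted_truth(SimulationConfig())
        assert planted_ordering(truth, "beta") == [set(PHASES)]

    def test_unknown_band_rejected(self):
        truth = build_planted_truth(SimulationConfig())
        with pytest.raises(InvalidConfigError):
            planted_ordering(truth, "ripple")


class TestSimulateBehavior:
    def test_same_seed_identical_records(self, tiny_sim_config):
        t1 = simulate_behavior_session(tiny_sim_config, 21)
        t2 = simulate_behavior_session(tiny_sim_config, 21)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            assert a.path_signature == b.path_signature
            assert np.array_equal(a.trajectory, b.trajectory)
            assert a.t_goal_s == b.t_goal_s

    def test_path_length_lower_bounds(self):
        cfg = SimulationConfig(trials_per_phase={p: 5 for p in PHASES})
        graph_distance = 6.0  # (0,0) -> (3,3) on the 4x4 grid
        for t in simulate_behavior_session(cfg, 22):
            length = compute_path_length(t)
            endpoints = np.linalg.norm(t.trajectory[-1, 1:] - t.trajectory[0, 1:])
            assert length >= endpoints - 1e-9
            assert length >= graph_distance - 1.0  # jitter slack

    def test_adjustment_trials_longer(self):
        cfg = SimulationConfig()
        trials = simulate_behavior_session(cfg, 23)
        dur = {p: [compute_duration(t) for t in trials if t.phase == p] for p in PHASES}
        assert np.mean(dur["adjustment"]) > np.mean(dur["acquisition"])
        _, p = ranksum(dur["adjustment"], dur["acquisition"])
        assert p < 0.001

    def test_all_trials_reach_goal(self, tiny_sim_config):
        for t in simulate_behavior_session(tiny_sim_config, 24):
            assert t.correct

    def test_unreachable_goal_rejected(self):
        # 1x4 line maze: blocking the edge next to the goal disconnects it
        cfg = SimulationConfig(
            maze=MazeSpec(
                shape=(1, 4),
                start=(0, 0),
                goal=(0, 3),
                blocked_edge=((0, 2), (0, 3)),
            )
        )
        with pytest.raises(InvalidMazeError):
            simulate_behavior_session(cfg, 0)

    def test_acquisition_and_recovery_same_graph_length(self):
        # the default maze admits an equal-length detour, so acquisition and
        # recovery route lengths are identically distributed
        cfg = SimulationConfig()
        trials = simulate_behavior_session(cfg, 25)
        n_edges = {
            p: {len(t.path_signature) for t in trials if t.phase == p}
            for p in PHASES
        }
        assert n_edges["acquisition"] == n_edges["recovery"] == {6}

    def test_planted_elongation_detected_in_95_of_100_replicates(self):
        # the planted adjustment-phase elongation of duration and path
        # length is significant (rank-sum) against both other phases at the
        # default effect size in at least 95 of 100 seeded sessions
        cfg = SimulationConfig()
        successes = 0
        for seed in range(100):
            trials = simulate_behavior_session(cfg, seed)
            dur = {p: [] for p in PHASES}
            plen = {p: [] for p in PHASES}
            for t in trials:
                dur[t.phase].append(compute_duration(t))
                plen[t.phase].append(compute_path_length(t))
            ok = True
            for vals in (dur, plen):
                ok &= np.mean(vals["adjustment"]) > np.mean(vals["acquisition"])
                ok &= np.mean(vals["adjustment"]) > np.mean(vals["recovery"])
                _, p1 = ranksum(vals["adjustment"], vals["acquisition"])
                _, p2 = ranksum(vals["adjustment"], vals["recovery"])
                ok &= p1 < 0.001 and p2 < 0.001
            successes += bool(ok)
        assert successes >= 95

    def test_phase_labels_follow_session_plan(self, tiny_sim_config):
        trials = simulate_behavior_session(tiny_sim_config, 26)
        assert [t.phase for t in trials] == (
            ["acquisition"] * 2 + ["adjustment"] * 2 + ["recovery"] * 2
        )
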