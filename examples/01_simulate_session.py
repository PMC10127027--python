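"""Simulate a synthetic detour-task session: multichannel LFP + behavior.

The generator plants phase-dependent band coupling (delta/theta depressed,
gamma elevated during path adjustment) and an adjustment-phase elongation of
trial duration and path length.  Everything is reproducible from (config,
seed).
"""

from hippoconn import (
    SimulationConfig,
    planted_ordering,
    simulate_behavior_session,
    simulate_lfp_session,
)
from hippoconn.synthetic import PHASES

config = SimulationConfig(
    trials_per_phase={p: 4 for p in PHASES},
    trial_duration_s=(6.0, 8.0),
)
recording, events, truth = simulate_lfp_session(config, seed=1)
trials = simulate_behavior_session(config, seed=1)

print(f"LFP: {recording.samples.shape[0]} samples x {recording.n_channels} channels "
      f"at {recording.sampling_rate_hz:.0f} Hz ({recording.duration_s:.1f} s)")
print(f"trials: {len(events)} ({', '.join(sorted({e.phase for e in events}))})")
for band in ("theta", "beta", "slow_gamma"):
    ordering = planted_ordering(truth, band)
    pretty = " < ".join("{" + ", ".join(sorted(s)) + "}" for s in ordering)
    print(f"planted {band:<10} connectivity ordering: {pretty}")
# The ordering is the ground truth the downstream coherence analysis must
# recover: for theta, adjustment sits strictly below the other two phases.
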