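"""From one trial's LFP window to a binarized theta functional network.

Magnitude-squared coherence Coh(f) = |p_xy|^2 / (p_x p_y) is averaged over
the FFT bins of the theta band (5-12 Hz) for every channel pair, and the
resulting matrix is thresholded into an unweighted network.
"""

import numpy as np

from hippoconn import (
    SimulationConfig,
    binarize,
    band_coherence_matrix,
    segment_soi,
    simulate_lfp_session,
)
from hippoconn.preprocess import DEFAULT_BANDS
from hippoconn.synthetic import PHASES

config = SimulationConfig(trials_per_phase={p: 1 for p in PHASES})
recording, events, _ = simulate_lfp_session(config, seed=2)
theta = DEFAULT_BANDS[1]

for event in (events[0], events[1]):  # one acquisition, one adjustment trial
    segment = segment_soi(recording, [event])[0]
    mat = band_coherence_matrix(segment, theta)
    net = binarize(mat, "absolute", 0.3)
    off = mat.matrix[np.triu_indices(mat.n_channels, k=1)]
    print(
        f"{event.phase:<12} mean theta coherence {off.mean():.3f}  "
        f"edges {net.n_edges}/{mat.n_channels * (mat.n_channels - 1) // 2}"
    )
# Coupling is planted high (0.8) in acquisition and low (0.2) in adjustment,
# so the acquisition network is dense and the adjustment network sparse.
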