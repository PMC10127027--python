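"""On-disk formats: recording matrix + JSON sidecar, CSV event/trajectory logs.

A recording is stored as a ``<stem>.npy`` (samples x channels, float64) next
to a ``<stem>.json`` sidecar carrying the sampling rate, channel labels,
units and generating seed.  Events and trajectories are plain CSV with the
headers ``trial_id, phase, t_start_s, t_end_s`` and ``trial_id, t_s, x, y``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .connectivity import BandCoherenceMatrix, BinaryNetwork
from .preprocess import LFPRecording, TrialEvent


def save_recording(
    recording: LFPRecording, directory: str | Path, stem: str = "lfp", seed: int | None = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}.npy", recording.samples)
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_labels": recording.channel_labels,
        "units": recording.units,
        "seed": seed,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return directory / f"{stem}.npy"


def load_recording(directory: str | Path, stem: str = "lfp") -> LFPRecording:
    directory = Path(directory)
    samples = np.load(directory / f"{stem}.npy")
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    return LFPRecording(
        samples=samples,
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        channel_labels=list(sidecar["channel_labels"]),
        units=sidecar.get("units", "uV"),
    )


def events_to_frame(events: Sequence[TrialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "phase": e.phase,
                "t_start_s": e.t_start_s,
                "t_end_s": e.t_end_s,
            }
            for e in events
        ]
    )


def events_from_frame(frame: pd.DataFrame) -> list[TrialEvent]:
    return [
        TrialEvent(
            trial_id=int(r.trial_id),
            phase=str(r.phase),
            t_start_s=float(r.t_start_s),
            t_end_s=float(r.t_end_s),
        )
        for r in frame.itertuples()
    ]


def trajectories_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for ts, x, y in t.trajectory:
            rows.append({"trial_id": t.trial_id, "t_s": ts, "x": x, "y": y})
    return pd.DataFrame(rows)


def matrix_to_csv(matrix: BandCoherenceMatrix, path: str | Path) -> None:
    labels = matrix.channel_labels or [str(i) for i in range(matrix.n_channels)]
    pd.DataFrame(matrix.matrix, index=labels, columns=labels).to_csv(path)


def network_to_edge_list(net: BinaryNetwork, path: str | Path) -> None:
    lines = [f"{i} {j}" for i, j in net.edge_list()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
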