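"""CSV dialects shared by the simulator, surrogate generator and estimator.

Spike trains travel as two-column CSV (``unit``, ``time_ms``), stimulus
trains as one-column CSV (``time_ms``); both are plain text so files can
be produced by any decomposition pipeline. Readers validate strict
monotonicity of discharge times per unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inputs import StimulusTrain
from .spikestats import SpikeTrain

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_stimulus_train",
    "write_stimulus_train",
]


def write_spike_trains(trains: dict[int, SpikeTrain], path) -> None:
    frames = [
        pd.DataFrame({"unit": unit, "time_ms": tr.times_ms})
        for unit, tr in sorted(trains.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spike_trains(
    path, duration_ms: float | None = None, source: str = "external"
) -> dict[int, SpikeTrain]:
    df = pd.read_csv(path)
    if not {"unit", "time_ms"}.issubset(df.columns):
        raise ValueError("spike CSV needs columns 'unit' and 'time_ms'")
    if duration_ms is None:
        duration_ms = float(df["time_ms"].max()) if len(df) else 0.0
    out: dict[int, SpikeTrain] = {}
    for unit, group in df.groupby("unit"):
        times = group["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"discharge times for unit {unit} are not increasing")
        out[int(unit)] = SpikeTrain(times, duration_ms, source=source)
    return out


def write_stimulus_train(train: StimulusTrain, path) -> None:
    pd.DataFrame({"time_ms": train.onsets_ms}).to_csv(path, index=False)


def read_stimulus_train(path, **epsc_kwargs) -> StimulusTrain:
    df = pd.read_csv(path)
    col = "time_ms" if "time_ms" in df.columns else df.columns[0]
    return StimulusTrain(df[col].to_numpy(dtype=float), **epsc_kwargs)
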