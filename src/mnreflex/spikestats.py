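"""Per-unit discharge statistics and inclusion filtering.

Background discharge rate (DR) is estimated from the 500 ms windows
immediately preceding each stimulus; the coefficient of variation of the
interspike intervals (CoV_ISI) is computed from ISIs that do not overlap
the 100 ms post-stimulus interval, so that evoked discharges do not
contaminate the background-noise index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs import StimulusTrain

__all__ = [
    "SpikeTrain",
    "DischargeStats",
    "UndefinedStatisticError",
    "background_dr",
    "background_isis",
    "cov_isi",
    "include_unit",
    "discharge_stats",
]

PRE_STIMULUS_DR_WINDOW_MS = 500.0
POST_STIMULUS_EXCLUSION_MS = 100.0

#: inclusion thresholds: minimum background DR (Hz) per analysis mode and the
#: shared CoV_ISI ceiling (%)
MIN_DR_HZ = {"simulated": 7.0, "experimental": 5.0}
MAX_COV_ISI_PCT = 30.0


class UndefinedStatisticError(ValueError):
    """Raised when a discharge statistic has no defined value."""


@dataclass(frozen=True)
class SpikeTrain:
    """Discharge times of one motor unit (ms, strictly increasing)."""

    times_ms: np.ndarray
    duration_ms: float
    source: str = "simulated"  # simulated | external | surrogate

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("discharge times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration_ms):
            raise ValueError("discharge times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times_ms.size)


@dataclass(frozen=True)
class DischargeStats:
    mean_dr_hz: float
    cov_isi_pct: float
    n_isis: int
    included: bool


def _pre_stimulus_windows(
    stimuli: StimulusTrain, window_ms: float
) -> list[tuple[float, float]]:
    """Union of [onset - window, onset) intervals, merged if overlapping."""
    raw = [(max(0.0, o - window_ms), o) for o in stimuli.onsets_ms]
    merged: list[tuple[float, float]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def background_dr(
    train: SpikeTrain,
    stimuli: StimulusTrain,
    window_ms: float = PRE_STIMULUS_DR_WINDOW_MS,
) -> float:
    """Mean background discharge rate (Hz) over pre-stimulus windows.

    Counts spikes inside the union of ``[onset - window, onset)`` intervals
    and divides by the total window time. A unit with no spikes has DR 0,
    so recruitment counting is total-ordered.
    """
    if stimuli.count < 1:
        raise UndefinedStatisticError("background DR needs at least one stimulus")
    windows = _pre_stimulus_windows(stimuli, window_ms)
    total_ms = sum(hi - lo for lo, hi in windows)
    if total_ms <= 0:
        raise UndefinedStatisticError("no pre-stimulus window available")
    t = train.times_ms
    count = sum(
        int(np.searchsorted(t, hi, "left") - np.searchsorted(t, lo, "left"))
        for lo, hi in windows
    )
    return 1000.0 * count / total_ms


def cov_isi(
    train: SpikeTrain,
    stimuli: StimulusTrain | None = None,
    exclusion_ms: float = POST_STIMULUS_EXCLUSION_MS,
) -> float:
    """CoV of interspike intervals (%), excluding reflex-perturbed ISIs.

    An ISI is excluded when the interval between its two spikes overlaps any
    ``(onset, onset + exclusion_ms]`` post-stimulus interval, so the statistic
    indexes background membrane noise rather than the evoked response.
    """
    isis = background_isis(train, stimuli, exclusion_ms)
    if isis.size < 3:
        raise UndefinedStatisticError("fewer than 3 ISIs after exclusion")
    mean = isis.mean()
    return 100.0 * isis.std() / mean


def background_isis(
    train: SpikeTrain,
    stimuli: StimulusTrain | None = None,
    exclusion_ms: float = POST_STIMULUS_EXCLUSION_MS,
) -> np.ndarray:
    """ISIs (ms) that do not overlap any post-stimulus exclusion interval."""
    t = train.times_ms
    if t.size < 2:
        return np.empty(0)
    starts, ends = t[:-1], t[1:]
    keep = np.ones(starts.size, dtype=bool)
    if stimuli is not None:
        for onset in stimuli.onsets_ms:
            keep &= ~((starts < onset + exclusion_ms) & (ends > onset))
    return ends[keep] - starts[keep]


def include_unit(stats: DischargeStats, mode: str = "simulated") -> bool:
    """Inclusion rule: DR above the mode's floor and CoV_ISI at most 30%.

    Simulated units require DR >= 7 Hz; externally recorded units use the
    looser 5 Hz floor (decomposition-quality screening is upstream of this
    package).
    """
    if mode not in MIN_DR_HZ:
        raise ValueError(f"unknown mode {mode!r}")
    return stats.mean_dr_hz >= MIN_DR_HZ[mode] and stats.cov_isi_pct <= MAX_COV_ISI_PCT


def discharge_stats(
    train: SpikeTrain,
    stimuli: StimulusTrain,
    mode: str = "simulated",
) -> DischargeStats:
    """Compute DR, CoV_ISI and the inclusion flag for one unit.

    Units whose CoV_ISI is undefined (too few ISIs) are never included; their
    CoV is reported as NaN.
    """
    dr = background_dr(train, stimuli)
    n_isis = int(background_isis(train, stimuli).size)
    try:
        cov = cov_isi(train, stimuli)
    except UndefinedStatisticError:
        cov = float("nan")
    stats = DischargeStats(dr, cov, n_isis, included=False)
    included = (not np.isnan(cov)) and include_unit(stats, mode)
    return DischargeStats(dr, cov, n_isis, included)
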