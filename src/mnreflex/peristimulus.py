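"""Peristimulus analysis: PSTH, PSF, cusum, error box and reflex metrics.

The peristimulus time histogram (PSTH) counts discharges in fixed bins
aligned to stimulus onset, aggregated over all stimuli. The peristimulus
frequencygram (PSF) instead accumulates the instantaneous discharge rate
(reciprocal of the preceding interspike interval) of every discharge
falling in the window. Reflex responses are read from the cumulative sum
(cusum) of the mean-subtracted per-bin values: an excitatory reflex
appears as a steep post-stimulus ramp whose height measures the evoked
extra discharge (PSTH, counts) or extra rate (PSF, Hz).

Significance uses the *error box*: the maximum absolute pre-stimulus
cusum deflection from zero. Only post-stimulus cusum excursions strictly
exceeding that deflection count as a significant response. Onset and end
of the response are found from the forward difference ("steepness") of
the cusum, thresholded at the largest absolute pre-stimulus forward
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs import StimulusTrain
from .spikestats import SpikeTrain

__all__ = [
    "Window",
    "PeristimulusData",
    "CusumTrace",
    "ReflexEstimate",
    "SIMULATED_WINDOW",
    "EXPERIMENTAL_WINDOW",
    "build_psth",
    "build_psf",
    "cusum",
    "error_box",
    "detect_reflex_auto",
    "estimate_reflex",
]


@dataclass(frozen=True)
class Window:
    """Peristimulus analysis window (ms before / after stimulus onset)."""

    pre_ms: float
    post_ms: float

    def __post_init__(self) -> None:
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ValueError("window extents must be positive")


#: analysis windows: recorded data use 200 ms pre / 100 ms post; simulated
#: data use the longer 300 ms pre / 150 ms post window.
EXPERIMENTAL_WINDOW = Window(pre_ms=200.0, post_ms=100.0)
SIMULATED_WINDOW = Window(pre_ms=300.0, post_ms=150.0)

#: in simulated mode (no conduction delay) the response must start within
#: 15 ms of the stimulus.
MAX_ONSET_MS = {"simulated": 15.0, "experimental": None}

DEFAULT_BIN_MS = 1.0

#: a cusum local maximum only counts as the response turning point if it is
#: not exceeded within this many ms (the reflex rise-time scale), so
#: sub-reflex wiggles do not truncate the response
TURNING_POINT_PATIENCE_MS = 3.0


@dataclass(frozen=True)
class PeristimulusData:
    """Binned peristimulus values: counts (PSTH) or summed rates (PSF).

    For the PSF, ``counts`` additionally records how many discharges fell
    in each bin; the cusum needs it to subtract the mean pre-stimulus
    frequency per discharge.
    """

    method: str  # "psth" | "psf"
    bin_edges_ms: np.ndarray  # relative to stimulus onset, len = n_bins + 1
    values: np.ndarray
    window: Window
    n_stimuli: int
    counts: np.ndarray | None = None

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def n_pre_bins(self) -> int:
        """Number of bins strictly before stimulus onset (edge at 0)."""
        return int(np.searchsorted(self.bin_edges_ms, 0.0, "left"))

    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


@dataclass(frozen=True)
class CusumTrace:
    """Cumulative sum of baseline-subtracted peristimulus values.

    ``baseline`` is the mean pre-stimulus count per bin (PSTH) or the
    mean pre-stimulus discharge frequency (PSF).
    """

    data: PeristimulusData
    baseline: float
    values: np.ndarray  # cusum after each bin; values[k] = sum_{j<=k}(v_j - baseline)

    @property
    def n_pre_bins(self) -> int:
        return self.data.n_pre_bins

    def forward_difference(self) -> np.ndarray:
        """Per-bin increment of the cusum (the mean-subtracted bin values)."""
        return np.diff(np.concatenate([[0.0], self.values]))


@dataclass(frozen=True)
class ReflexEstimate:
    """Reflex response metrics from a cusum trace."""

    method: str
    significant: bool
    onset_ms: float
    end_ms: float
    latency_ms: float
    duration_ms: float
    amplitude: float  # counts (PSTH) or Hz (PSF)
    normalized_amplitude: float  # amplitude / number of stimuli
    error_box: float
    slope_threshold: float


def _bin_edges(window: Window, bin_ms: float) -> np.ndarray:
    n_pre = int(round(window.pre_ms / bin_ms))
    n_post = int(round(window.post_ms / bin_ms))
    if not np.isclose(n_pre * bin_ms, window.pre_ms) or not np.isclose(
        n_post * bin_ms, window.post_ms
    ):
        raise ValueError("bin width must divide both window extents")
    return np.arange(-n_pre, n_post + 1) * bin_ms


def build_psth(
    train: SpikeTrain,
    stimuli: StimulusTrain,
    window: Window = SIMULATED_WINDOW,
    bin_ms: float = DEFAULT_BIN_MS,
) -> PeristimulusData:
    """Spike counts per peristimulus bin, aggregated over all stimuli."""
    if stimuli.count < 1:
        raise ValueError("PSTH requires at least one stimulus")
    edges = _bin_edges(window, bin_ms)
    counts = np.zeros(edges.size - 1)
    t = train.times_ms
    for onset in stimuli.onsets_ms:
        rel = t[(t >= onset - window.pre_ms) & (t < onset + window.post_ms)] - onset
        if rel.size:
            counts += np.histogram(rel, bins=edges)[0]
    return PeristimulusData("psth", edges, counts, window, stimuli.count)


def build_psf(
    train: SpikeTrain,
    stimuli: StimulusTrain,
    window: Window = SIMULATED_WINDOW,
    bin_ms: float = DEFAULT_BIN_MS,
) -> PeristimulusData:
    """Summed instantaneous discharge rates per peristimulus bin.

    Each discharge at peristimulus time t contributes ``1000 / ISI`` Hz,
    where ISI is the interval to the immediately preceding discharge, to
    the bin containing t. The first discharge of a recording has no
    preceding ISI and is skipped.
    """
    if stimuli.count < 1:
        raise ValueError("PSF requires at least one stimulus")
    edges = _bin_edges(window, bin_ms)
    values = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1)
    t = train.times_ms
    if t.size < 2:
        return PeristimulusData("psf", edges, values, window, stimuli.count, counts)
    rates_hz = 1000.0 / np.diff(t)  # rate attached to spikes t[1:]
    spikes, rates = t[1:], rates_hz
    for onset in stimuli.onsets_ms:
        sel = (spikes >= onset - window.pre_ms) & (spikes < onset + window.post_ms)
        if not np.any(sel):
            continue
        rel = spikes[sel] - onset
        idx = np.digitize(rel, edges) - 1
        np.add.at(values, idx, rates[sel])
        np.add.at(counts, idx, 1.0)
    return PeristimulusData("psf", edges, values, window, stimuli.count, counts)


def cusum(data: PeristimulusData) -> CusumTrace:
    """Cumulative sum of baseline-subtracted peristimulus values.

    PSTH: the baseline is the mean pre-stimulus *per-bin* count, so the
    cusum accumulates ``count(j) - mean_count``. PSF: the baseline is the
    mean pre-stimulus discharge *frequency*, subtracted from every
    discharge's instantaneous frequency, so bin j contributes
    ``sum_rates(j) - n_spikes(j) * mean_rate``. In both cases the cusum
    returns exactly to zero at the last pre-stimulus bin by construction,
    so any systematic post-stimulus ramp stands out against the
    mean-free baseline.
    """
    n_pre = data.n_pre_bins
    if n_pre < 1:
        raise ValueError("cusum requires a non-empty pre-stimulus region")
    if data.method == "psf":
        if data.counts is None:
            raise ValueError("PSF cusum needs per-bin spike counts")
        n_pre_spikes = data.counts[:n_pre].sum()
        baseline = (
            float(data.values[:n_pre].sum() / n_pre_spikes)
            if n_pre_spikes > 0
            else 0.0
        )
        values = np.cumsum(data.values - data.counts * baseline)
    else:
        baseline = float(data.values[:n_pre].mean())
        values = np.cumsum(data.values - baseline)
    return CusumTrace(data, baseline, values)


def error_box(c: CusumTrace) -> float:
    """Significance threshold: max absolute pre-stimulus cusum deflection."""
    return float(np.abs(c.values[: c.n_pre_bins]).max())


def max_post_stimulus_cusum(c: CusumTrace) -> float:
    """Largest post-stimulus cusum value (for diagnostics)."""
    post = c.values[c.n_pre_bins:]
    return float(post.max()) if post.size else 0.0


def detect_reflex_auto(c: CusumTrace, mode: str = "simulated") -> ReflexEstimate:
    """Automated reflex onset/end/amplitude from cusum steepness.

    The slope threshold is the largest absolute pre-stimulus forward
    difference of the cusum. The response onset is the first post-stimulus
    bin whose forward difference strictly exceeds that threshold (within
    15 ms of the stimulus in simulated mode); the response end is the last
    bin of the contiguous supra-threshold run. The amplitude is the cusum
    rise from onset to the first turning point (local maximum of the cusum)
    at or after the response end; ties take the earliest bin. Amplitudes are
    normalized by the number of stimuli, expressing the extra count (PSTH)
    or extra rate (PSF) evoked per stimulation.

    Significance is excitatory-only and response-tied: the cusum value at
    the response turning point must strictly exceed the error box (the
    maximum pre-stimulus deflection from zero). A post-stimulus excursion
    away from the detected response does not count.
    """
    if mode not in MAX_ONSET_MS:
        raise ValueError(f"unknown mode {mode!r}")
    data = c.data
    n_pre = c.n_pre_bins
    box = error_box(c)
    diffs = c.forward_difference()
    slope_thr = float(np.abs(diffs[:n_pre]).max())
    edges = data.bin_edges_ms

    max_onset = MAX_ONSET_MS[mode]
    null = ReflexEstimate(
        data.method, False, float("nan"), float("nan"), float("nan"),
        float("nan"), 0.0, 0.0, box, slope_thr,
    )

    post_bins = np.arange(n_pre, data.values.size)
    supra = diffs[post_bins] > slope_thr
    if max_onset is not None:
        supra &= edges[post_bins] < max_onset  # onset must begin within limit
    if not np.any(supra):
        return null
    onset_bin = int(post_bins[np.argmax(supra)])

    # contiguous supra-threshold run starting at onset (beyond the onset
    # limit the run may continue; only the onset is constrained)
    end_bin = onset_bin
    while end_bin + 1 < data.values.size and diffs[end_bin + 1] > slope_thr:
        end_bin += 1

    # first turning point at/after end of rise: earliest bin whose cusum is
    # not exceeded within the patience window (earliest bin wins on ties)
    patience = max(1, int(round(TURNING_POINT_PATIENCE_MS / data.bin_width_ms)))
    peak_bin = end_bin
    while True:
        ahead = c.values[peak_bin + 1 : peak_bin + 1 + patience]
        if ahead.size == 0 or ahead.max() <= c.values[peak_bin]:
            break
        peak_bin = peak_bin + 1 + int(np.argmax(ahead))

    onset_ms = float(edges[onset_bin])
    end_ms = float(edges[end_bin + 1])
    cusum_before_onset = c.values[onset_bin - 1] if onset_bin > 0 else 0.0
    amplitude = float(c.values[peak_bin] - cusum_before_onset)
    normalized = amplitude / data.n_stimuli
    significant = bool(c.values[peak_bin] > box)
    return ReflexEstimate(
        method=data.method,
        significant=significant,
        onset_ms=onset_ms,
        end_ms=end_ms,
        latency_ms=onset_ms,
        duration_ms=end_ms - onset_ms,
        amplitude=amplitude,
        normalized_amplitude=normalized,
        error_box=box,
        slope_threshold=slope_thr,
    )


def estimate_reflex(
    train: SpikeTrain,
    stimuli: StimulusTrain,
    method: str = "psf",
    mode: str = "simulated",
    window: Window | None = None,
    bin_ms: float = DEFAULT_BIN_MS,
) -> ReflexEstimate:
    """One-call pipeline: binning -> cusum -> automated reflex detection."""
    if window is None:
        window = SIMULATED_WINDOW if mode == "simulated" else EXPERIMENTAL_WINDOW
    builder = build_psf if method == "psf" else build_psth
    if method not in ("psf", "psth"):
        raise ValueError(f"unknown method {method!r}")
    data = builder(train, stimuli, window, bin_ms)
    return detect_reflex_auto(cusum(data), mode)
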