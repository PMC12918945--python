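"""Synaptic input synthesis for the motor neuron pool.

Every neuron in the pool receives the linear sum of three current
components, all expressed as effective synaptic currents at the soma:

* a *common* drive shared by the whole pool: a constant mean plus
  zero-mean band-pass filtered (15-35 Hz, 4th-order Butterworth)
  Gaussian noise whose SD is a fixed fraction (default 20%) of the mean;
* an *independent* noise component per neuron: zero-mean low-pass
  filtered (<100 Hz, 2nd-order Butterworth) Gaussian noise, scaled so
  that it carries a fixed share (default 20%) of the total noise
  variance;
* the reflex *stimulus*: an excitatory postsynaptic current (EPSC)
  transient repeated at roughly one-second intervals.

Times are in milliseconds, currents in nA, frequencies in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "InputConfig",
    "StimulusTrain",
    "CurrentTrace",
    "epsc_waveform",
    "generate_common_input",
    "generate_independent_noise",
    "generate_stimulus_train",
    "stimulus_component",
    "assemble_input",
]

#: grid (ms) on which noise is synthesised before interpolation; the noise
#: is band-limited below 100 Hz, so a 1 kHz synthesis grid resolves it fully.
NOISE_SYNTHESIS_DT_MS = 1.0


class ConfigurationError(ValueError):
    """Raised for invalid input-synthesis configurations."""


@dataclass(frozen=True)
class InputConfig:
    """Configuration of the common drive and independent noise.

    ``common_noise_frac`` is the SD of the common noise as a fraction of
    ``mean_drive_nA``. ``independent_share`` is the share of the *total*
    noise contributed by the independent component; it is interpreted as
    a variance share when ``share_mode == "variance"`` (default) and as
    an SD share when ``share_mode == "sd"``.
    """

    mean_drive_nA: float = 10.0
    duration_ms: float = 10_000.0
    dt_ms: float = 0.05
    common_band_hz: tuple[float, float] = (15.0, 35.0)
    common_filter_order: int = 4
    common_noise_frac: float = 0.20
    independent_cutoff_hz: float = 100.0
    independent_filter_order: int = 2
    independent_share: float = 0.20
    share_mode: str = "variance"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.common_band_hz
        nyq = 500.0 / NOISE_SYNTHESIS_DT_MS
        if not (0.0 < lo < hi < nyq):
            raise ConfigurationError(
                f"common band {self.common_band_hz} Hz must satisfy "
                f"0 < low < high < {nyq} Hz"
            )
        if not (0.0 < self.independent_cutoff_hz < nyq):
            raise ConfigurationError("independent-noise cutoff above Nyquist")
        if not (0.0 <= self.common_noise_frac <= 1.0):
            raise ConfigurationError("common_noise_frac must lie in [0, 1]")
        if not (0.0 <= self.independent_share <= 1.0):
            raise ConfigurationError("independent_share must lie in [0, 1]")
        if self.share_mode not in ("variance", "sd"):
            raise ConfigurationError("share_mode must be 'variance' or 'sd'")
        if self.dt_ms <= 0 or self.duration_ms <= 0:
            raise ConfigurationError("dt_ms and duration_ms must be positive")

    @property
    def common_noise_sd_nA(self) -> float:
        return self.common_noise_frac * self.mean_drive_nA

    @property
    def independent_noise_sd_nA(self) -> float:
        """SD of the independent component implied by the configured share.

        With variance shares, common variance is ``1 - share`` of the total,
        so ``sd_indep = sd_common * sqrt(share / (1 - share))``; the default
        20% variance share gives ``sd_indep = 0.5 * sd_common``.
        """
        s = self.independent_share
        if s == 0.0:
            return 0.0
        if s == 1.0:
            raise ConfigurationError(
                "independent_share of 1 leaves no common noise to scale from"
            )
        if self.share_mode == "variance":
            return self.common_noise_sd_nA * np.sqrt(s / (1.0 - s))
        return self.common_noise_sd_nA * s / (1.0 - s)


@dataclass(frozen=True)
class StimulusTrain:
    """Reflex stimulus onsets plus the EPSC shape they trigger."""

    onsets_ms: np.ndarray
    epsc_gain_nA: float = 6.0
    epsc_tau_ms: float = 1.0
    epsc_duration_ms: float = 40.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ConfigurationError("stimulus onsets must be strictly increasing")
        if onsets.size and np.any(np.diff(onsets) <= self.epsc_duration_ms):
            raise ConfigurationError(
                "inter-stimulus intervals must exceed the EPSC duration"
            )

    @property
    def count(self) -> int:
        return int(self.onsets_ms.size)


@dataclass
class CurrentTrace:
    """A sampled current signal on a fixed time grid (ms, nA)."""

    dt_ms: float
    values: np.ndarray
    label: str = "total"
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * self.values.size

    def time_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_ms


def epsc_waveform(
    t_ms: float | np.ndarray,
    gain_nA: float = 6.0,
    tau_ms: float = 1.0,
    duration_ms: float = 40.0,
) -> float | np.ndarray:
    """Alpha-function EPSC: ``gain * (t/tau) * exp(1 - t/tau)``.

    The waveform peaks at exactly ``gain_nA`` at ``t = tau_ms`` and is
    truncated to zero beyond ``duration_ms`` (by which point it has decayed
    to ~1e-15 of the peak for the default time constant).
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("epsc_waveform is defined for t >= 0 only")
    x = t / tau_ms
    out = gain_nA * x * np.exp(1.0 - x)
    out = np.where(t <= duration_ms, out, 0.0)
    if np.isscalar(t_ms):
        return float(out)
    return out


def _synth_filtered_noise(
    rng: np.random.Generator,
    n_coarse: int,
    sos: np.ndarray,
    target_sd: float,
) -> np.ndarray:
    """White Gaussian noise -> zero-phase filter -> rescale to target SD."""
    white = rng.standard_normal(n_coarse)
    filtered = signal.sosfiltfilt(sos, white)
    sd = filtered.std()
    if sd == 0.0 or target_sd == 0.0:
        return np.zeros(n_coarse)
    return filtered * (target_sd / sd)


def _coarse_grid_size(duration_ms: float) -> int:
    # extra samples so interpolation covers the last fine-grid point
    return int(np.ceil(duration_ms / NOISE_SYNTHESIS_DT_MS)) + 2


def _interp_to_grid(coarse: np.ndarray, dt_ms: float, n: int) -> np.ndarray:
    t_fine = np.arange(n) * dt_ms
    t_coarse = np.arange(coarse.size) * NOISE_SYNTHESIS_DT_MS
    return np.interp(t_fine, t_coarse, coarse)


def common_noise_sos(cfg: InputConfig) -> np.ndarray:
    fs = 1000.0 / NOISE_SYNTHESIS_DT_MS
    return signal.butter(
        cfg.common_filter_order, cfg.common_band_hz, btype="bandpass",
        fs=fs, output="sos",
    )


def independent_noise_sos(cfg: InputConfig) -> np.ndarray:
    fs = 1000.0 / NOISE_SYNTHESIS_DT_MS
    return signal.butter(
        cfg.independent_filter_order, cfg.independent_cutoff_hz,
        btype="lowpass", fs=fs, output="sos",
    )


def generate_common_noise_coarse(cfg: InputConfig) -> np.ndarray:
    """Zero-mean common noise on the 1 ms synthesis grid (no mean drive)."""
    rng = np.random.default_rng(cfg.seed)
    n_coarse = _coarse_grid_size(cfg.duration_ms)
    if cfg.common_noise_sd_nA == 0.0:
        return np.zeros(n_coarse)
    return _synth_filtered_noise(
        rng, n_coarse, common_noise_sos(cfg), cfg.common_noise_sd_nA
    )


def generate_independent_noise_coarse(
    cfg: InputConfig, neuron_seed: int
) -> np.ndarray:
    """Zero-mean independent noise for one neuron on the synthesis grid."""
    rng = np.random.default_rng(neuron_seed)
    n_coarse = _coarse_grid_size(cfg.duration_ms)
    if cfg.independent_noise_sd_nA == 0.0:
        return np.zeros(n_coarse)
    return _synth_filtered_noise(
        rng, n_coarse, independent_noise_sos(cfg), cfg.independent_noise_sd_nA
    )


def generate_common_input(cfg: InputConfig) -> CurrentTrace:
    """Common drive: constant mean plus band-passed Gaussian noise.

    The noise is synthesised on a 1 ms grid (it is band limited well below
    the 500 Hz Nyquist of that grid), rescaled to the exact target SD after
    zero-phase filtering, then linearly interpolated to ``cfg.dt_ms``.
    """
    n = int(round(cfg.duration_ms / cfg.dt_ms))
    noise = _interp_to_grid(generate_common_noise_coarse(cfg), cfg.dt_ms, n)
    return CurrentTrace(cfg.dt_ms, cfg.mean_drive_nA + noise, label="common")


def generate_independent_noise(cfg: InputConfig, neuron_seed: int) -> CurrentTrace:
    """Per-neuron low-pass-filtered zero-mean Gaussian noise."""
    n = int(round(cfg.duration_ms / cfg.dt_ms))
    noise = _interp_to_grid(
        generate_independent_noise_coarse(cfg, neuron_seed), cfg.dt_ms, n
    )
    return CurrentTrace(cfg.dt_ms, noise, label="independent")


def generate_stimulus_train(
    count: int = 200,
    isi_mean_ms: float = 1000.0,
    isi_sd_ms: float = 100.0,
    isi_min_ms: float = 200.0,
    start_ms: float = 1000.0,
    seed: int = 0,
    epsc_gain_nA: float = 6.0,
    epsc_tau_ms: float = 1.0,
    epsc_duration_ms: float = 40.0,
) -> StimulusTrain:
    """Stimulus onsets with Gaussian inter-stimulus intervals.

    Intervals are drawn from N(isi_mean, isi_sd) and truncated below at
    ``isi_min_ms`` so consecutive EPSCs can never overlap.
    """
    if count < 1:
        raise ConfigurationError("stimulus count must be >= 1")
    rng = np.random.default_rng(seed)
    isis = rng.normal(isi_mean_ms, isi_sd_ms, size=count - 1)
    isis = np.maximum(isis, isi_min_ms)
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(isis)])
    return StimulusTrain(
        onsets_ms=onsets,
        epsc_gain_nA=epsc_gain_nA,
        epsc_tau_ms=epsc_tau_ms,
        epsc_duration_ms=epsc_duration_ms,
    )


def stimulus_component(
    train: StimulusTrain, dt_ms: float, n_samples: int
) -> np.ndarray:
    """Sampled EPSC train on a fine grid: sum_k epsc(t - onset_k)."""
    out = np.zeros(n_samples)
    n_wave = int(round(train.epsc_duration_ms / dt_ms)) + 1
    for onset in train.onsets_ms:
        i0 = int(np.ceil(onset / dt_ms - 1e-9))
        if i0 >= n_samples:
            break
        i1 = min(i0 + n_wave, n_samples)
        # evaluate at the actual grid offsets so non-grid-aligned onsets work
        seg_t = np.arange(i0, i1) * dt_ms - onset
        out[i0:i1] += np.asarray(
            epsc_waveform(
                seg_t, train.epsc_gain_nA, train.epsc_tau_ms, train.epsc_duration_ms
            )
        )
    return out


def assemble_input(
    common: CurrentTrace,
    independent: CurrentTrace,
    train: StimulusTrain | None = None,
) -> CurrentTrace:
    """Linearly sum the input components on a shared time grid."""
    if common.dt_ms != independent.dt_ms or common.values.size != independent.values.size:
        raise ConfigurationError("component time grids do not match")
    stim = (
        stimulus_component(train, common.dt_ms, common.values.size)
        if train is not None
        else np.zeros(common.values.size)
    )
    total = common.values + independent.values + stim
    return CurrentTrace(
        common.dt_ms,
        total,
        label="total",
        components={
            "common": common.values,
            "independent": independent.values,
            "stimulus": stim,
        },
    )


def config_for_level(
    base: InputConfig, mean_drive_nA: float, seed: int
) -> InputConfig:
    """Derive a per-activation-level configuration from a base config."""
    return replace(base, mean_drive_nA=mean_drive_nA, seed=seed)
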