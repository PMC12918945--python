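"""Motor neuron pool construction and membrane simulation.

A pool is an ordered set of two-compartment conductance-based motor
neurons derived from one reference neuron: neuron i's passive and AHP
conductances are multiplied by a size factor ``sigma_i`` (so its input
resistance is ``R_ref / sigma_i`` and its rheobase is ``sigma_i`` times
the reference rheobase), while its compartment capacitances and spike
conductances follow a separate, much weaker capacitance factor. Size
factors are chosen so target rheobase is exponential in the neuron
index (the size principle): small indices are small, high-resistance,
low-threshold neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import _kernel
from .inputs import CurrentTrace, StimulusTrain, epsc_waveform
from .params import REFERENCE_NEURON, NeuronConstants, SizeDistribution

__all__ = [
    "MNParameters",
    "MNPool",
    "MembraneTrace",
    "IntegrationError",
    "build_pool",
    "simulate_mn",
    "f_i_curve",
    "rheobase",
    "reference_rheobase",
]

DEFAULT_DT_MS = 0.05
DEFAULT_N_MNS = 200


class IntegrationError(RuntimeError):
    """Raised when the membrane integration produces non-finite state."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MNParameters:
    """Per-neuron electrical parameters (a scaled reference neuron).

    ``size_factor`` scales every membrane conductance (so input resistance
    falls as 1/size), while ``capacitance_factor`` scales the compartment
    capacitances. The two are decoupled because motor neuron size
    differences are carried mainly by the dendritic membrane conductance,
    whereas the effective somatic capacitance charged by a millisecond
    EPSC varies far less across the pool.
    """

    index: int  # 1-based, ordered by size (1 = smallest = highest R)
    size_factor: float
    target_rheobase_nA: float
    capacitance_factor: float = 1.0
    constants: NeuronConstants = REFERENCE_NEURON

    def __post_init__(self) -> None:
        if self.size_factor <= 0 or self.capacitance_factor <= 0:
            raise ConfigurationError("scale factors must be positive")

    @property
    def c_div(self) -> float:
        """Reference-frame capacitance multiplier used by the integrator."""
        return self.capacitance_factor / self.size_factor

    @property
    def soma_input_resistance_MOhm(self) -> float:
        return self.constants.input_resistance_MOhm / self.size_factor

    @property
    def g_coupling_uS(self) -> float:
        return self.constants.g_coupling_uS * self.size_factor

    @property
    def g_leak_soma_uS(self) -> float:
        return self.constants.g_leak_soma_uS * self.size_factor

    @property
    def c_soma_nF(self) -> float:
        return self.constants.c_soma_nF * self.capacitance_factor

    @property
    def c_dend_nF(self) -> float:
        return self.constants.c_dend_nF * self.capacitance_factor

    def scaled_dict(self) -> dict:
        """All electrical parameters with size scaling applied."""
        d = self.constants.as_dict()
        for key in (
            "g_leak_soma_uS", "g_leak_dend_uS",
            "g_coupling_uS", "g_na_uS", "g_kf_uS", "g_ks_uS",
        ):
            d[key] = d[key] * self.size_factor
        for key in ("c_soma_nF", "c_dend_nF"):
            d[key] = d[key] * self.capacitance_factor
        d["index"] = self.index
        d["size_factor"] = self.size_factor
        d["capacitance_factor"] = self.capacitance_factor
        d["soma_input_resistance_MOhm"] = self.soma_input_resistance_MOhm
        d["target_rheobase_nA"] = self.target_rheobase_nA
        return d


@dataclass(frozen=True)
class MNPool:
    """An ordered motor neuron pool with exponential size distribution."""

    neurons: tuple[MNParameters, ...]
    distribution: SizeDistribution
    seed: int
    constants: NeuronConstants = REFERENCE_NEURON

    @property
    def n(self) -> int:
        return len(self.neurons)

    def size_factors(self) -> np.ndarray:
        return np.array([mn.size_factor for mn in self.neurons])

    def input_resistances_MOhm(self) -> np.ndarray:
        return np.array([mn.soma_input_resistance_MOhm for mn in self.neurons])

    def target_rheobases_nA(self) -> np.ndarray:
        return np.array([mn.target_rheobase_nA for mn in self.neurons])

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "distribution": {
                "anchor_low_index": self.distribution.anchor_low_index,
                "anchor_low_rheobase_nA": self.distribution.anchor_low_rheobase_nA,
                "anchor_high_index": self.distribution.anchor_high_index,
                "anchor_high_rheobase_nA": self.distribution.anchor_high_rheobase_nA,
                "exponent_scale": self.distribution.exponent_scale,
                "capacitance_exponent": self.distribution.capacitance_exponent,
            },
            "reference_neuron": self.constants.as_dict(),
            "neurons": [mn.scaled_dict() for mn in self.neurons],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class MembraneTrace:
    """Simulated membrane state of one neuron on a fixed time grid."""

    dt_ms: float
    soma_mV: np.ndarray
    dendrite_mV: np.ndarray
    gates: np.ndarray  # rows: m, h, n, q
    spike_times_ms: np.ndarray

    def time_ms(self) -> np.ndarray:
        return np.arange(self.soma_mV.size) * self.dt_ms

    def to_csv(self, path, spikes_path=None) -> None:
        """Write (time, soma, dendrite) as CSV; optionally the spike times
        as a one-column CSV in milliseconds."""
        import pandas as pd

        pd.DataFrame(
            {
                "time_ms": self.time_ms(),
                "soma_mV": self.soma_mV,
                "dendrite_mV": self.dendrite_mV,
            }
        ).to_csv(path, index=False)
        if spikes_path is not None:
            pd.DataFrame({"spike_time_ms": self.spike_times_ms}).to_csv(
                spikes_path, index=False
            )


_REF_RHEOBASE_CACHE: dict[NeuronConstants, float] = {}


def _fires_sustained(
    constants: NeuronConstants,
    sigma: float,
    current_nA: float,
    c_div: float = 1.0,
    dt_ms: float = DEFAULT_DT_MS,
    sim_ms: float = 3000.0,
    settle_ms: float = 2000.0,
) -> bool:
    """True if a constant current keeps the neuron firing past the settle time."""
    p = _kernel.pack_params(constants)
    n_steps = int(round(sim_ms / dt_ms))
    current = np.full(n_steps, current_nA)
    *_, count, times, diverged = _kernel.integrate_single(
        dt_ms, p, sigma, c_div, current, max_spikes=int(sim_ms / 1000 * 200) + 8
    )
    if diverged:
        raise IntegrationError(
            f"integration diverged at {current_nA} nA (size factor {sigma})"
        )
    return count > 0 and times[:count][-1] >= settle_ms


def rheobase(
    params: MNParameters | NeuronConstants,
    tolerance_nA: float = 0.01,
    dt_ms: float = DEFAULT_DT_MS,
) -> float:
    """Bisection estimate of the minimal constant current giving sustained firing."""
    if tolerance_nA <= 0:
        raise ConfigurationError("tolerance must be positive")
    if isinstance(params, MNParameters):
        constants, sigma, c_div = params.constants, params.size_factor, params.c_div
    else:
        constants, sigma, c_div = params, 1.0, 1.0
    lo = 0.0
    hi = 2.0 * sigma
    for _ in range(12):
        if _fires_sustained(constants, sigma, hi, c_div, dt_ms):
            break
        lo = hi
        hi *= 2.0
    else:
        raise ConfigurationError(
            f"no sustained firing up to {hi} nA; bad model parameters?"
        )
    while hi - lo > tolerance_nA:
        mid = 0.5 * (lo + hi)
        if _fires_sustained(constants, sigma, mid, c_div, dt_ms):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def reference_rheobase(
    constants: NeuronConstants = REFERENCE_NEURON,
    tolerance_nA: float = 0.005,
) -> float:
    """Rheobase of the unit-size reference neuron (cached)."""
    if constants not in _REF_RHEOBASE_CACHE:
        _REF_RHEOBASE_CACHE[constants] = rheobase(constants, tolerance_nA)
    return _REF_RHEOBASE_CACHE[constants]


def build_pool(
    n_mns: int = DEFAULT_N_MNS,
    distribution: SizeDistribution | None = None,
    seed: int = 0,
    constants: NeuronConstants = REFERENCE_NEURON,
    indices=None,
) -> MNPool:
    """Build a pool ordered by decreasing input resistance.

    Size factors are deterministic given the distribution descriptor: the
    target rheobase profile is exponential in the index and anchored so
    that the calibrated recruitment fractions hold under the default noisy
    drive (see ``SizeDistribution``). ``seed`` is recorded for input
    generation downstream; pool construction itself is deterministic.

    ``indices`` selects an explicit subset of the 1-based index range
    (e.g. ``range(1, 201, 4)`` for a reduced pool spanning the full size
    range); by default the pool is neurons ``1..n_mns``.
    """
    if indices is None:
        indices = range(1, n_mns + 1)
    indices = list(indices)
    if len(indices) < 1:
        raise ConfigurationError("pool needs at least one neuron")
    if any(i < 1 for i in indices) or sorted(indices) != indices:
        raise ConfigurationError("indices must be increasing and 1-based")
    distribution = distribution or SizeDistribution()
    rho_ref = reference_rheobase(constants)
    neurons = []
    for i in indices:
        rho = distribution.rheobase_nA(i)
        sigma = rho / rho_ref
        neurons.append(
            MNParameters(
                index=i,
                size_factor=sigma,
                target_rheobase_nA=rho,
                capacitance_factor=sigma ** distribution.capacitance_exponent,
                constants=constants,
            )
        )
    return MNPool(tuple(neurons), distribution, seed, constants)


def simulate_mn(
    params: MNParameters,
    input_trace: CurrentTrace,
    dt_ms: float | None = None,
) -> MembraneTrace:
    """Integrate one neuron's membrane dynamics under an injected current.

    Deterministic for fixed parameters and input; spike times are the
    upward crossings of the detection threshold (0 mV) with a 1 ms lockout.
    """
    dt = input_trace.dt_ms if dt_ms is None else dt_ms
    if dt_ms is not None and not math.isclose(dt_ms, input_trace.dt_ms):
        raise ConfigurationError("input trace must be sampled at the requested dt")
    if dt > 0.1:
        raise ConfigurationError("dt must be <= 0.1 ms to resolve the EPSC rise")
    p = _kernel.pack_params(params.constants)
    duration_s = input_trace.duration_ms / 1000.0
    max_spikes = int(duration_s * 200) + 16
    vs, vd, gates, count, times, diverged = _kernel.integrate_single(
        dt, p, params.size_factor, params.c_div,
        np.ascontiguousarray(input_trace.values, float), max_spikes,
    )
    if diverged:
        t_div = float(np.argmax(~np.isfinite(vs)) * dt)
        raise IntegrationError(
            f"integration diverged for neuron {params.index} at t = {t_div:.2f} ms"
        )
    return MembraneTrace(dt, vs, vd, gates, times[:count].copy())


def f_i_curve(
    params: MNParameters,
    currents_nA,
    sim_s: float = 6.0,
    transient_s: float = 1.0,
    dt_ms: float = DEFAULT_DT_MS,
) -> list[tuple[float, float]]:
    """Noiseless current-frequency relation: mean DR per constant current.

    Each point discards an initial transient and averages the discharge
    rate over the remaining ``sim_s - transient_s`` seconds.
    """
    currents = np.asarray(currents_nA, dtype=float)
    if np.any(np.diff(currents) <= 0):
        raise ConfigurationError("currents must be sorted ascending")
    p = _kernel.pack_params(params.constants)
    n_steps = int(round(sim_s * 1000.0 / dt_ms))
    out = []
    for cur in currents:
        trace = np.full(n_steps, cur)
        *_, count, times, diverged = _kernel.integrate_single(
            dt_ms, p, params.size_factor, params.c_div, trace,
            max_spikes=int(sim_s * 200) + 8,
        )
        if diverged:
            raise IntegrationError(
                f"integration diverged for neuron {params.index} at {cur} nA"
            )
        spikes = times[:count]
        n_late = int((spikes >= transient_s * 1000.0).sum())
        out.append((float(cur), n_late / (sim_s - transient_s)))
    return out


def run_pool_kernel(
    pool: MNPool,
    i_mean_nA: float,
    common_coarse: np.ndarray,
    indep_coarse: np.ndarray,
    duration_ms: float,
    stimuli: StimulusTrain | None = None,
    dt_ms: float = DEFAULT_DT_MS,
    noise_dt_ms: float = 1.0,
) -> list[np.ndarray]:
    """Integrate every pool neuron; returns per-neuron spike-time arrays.

    ``common_coarse`` and ``indep_coarse`` are noise traces on the coarse
    noise grid; the kernel interpolates them to the integration grid.
    """
    n_steps = int(round(duration_ms / dt_ms))
    stride = int(round(noise_dt_ms / dt_ms))
    needed = n_steps // stride + 2
    if common_coarse.size < needed or indep_coarse.shape[1] < needed:
        raise ConfigurationError("noise traces shorter than the simulation")
    if indep_coarse.shape[0] != pool.n:
        raise ConfigurationError("independent noise must have one row per neuron")
    if stimuli is not None and stimuli.count:
        stim_steps = np.round(stimuli.onsets_ms / dt_ms).astype(np.int64)
        n_wave = int(round(stimuli.epsc_duration_ms / dt_ms)) + 1
        epsc = np.asarray(
            epsc_waveform(
                np.arange(n_wave) * dt_ms,
                stimuli.epsc_gain_nA,
                stimuli.epsc_tau_ms,
                stimuli.epsc_duration_ms,
            )
        )
    else:
        stim_steps = np.empty(0, dtype=np.int64)
        epsc = np.zeros(1)
    max_spikes = int(duration_ms / 1000.0 * 200) + 16
    counts, times, diverged = _kernel.integrate_pool(
        dt_ms,
        n_steps,
        _kernel.pack_params(pool.constants),
        pool.size_factors(),
        np.array([mn.c_div for mn in pool.neurons]),
        i_mean_nA,
        np.ascontiguousarray(common_coarse, dtype=float),
        np.ascontiguousarray(indep_coarse, dtype=float),
        stride,
        epsc,
        stim_steps,
        max_spikes,
    )
    if np.any(diverged):
        bad = int(np.argmax(diverged)) + 1
        raise IntegrationError(f"integration diverged for neuron {bad}")
    return [times[i, : min(counts[i], max_spikes)].copy() for i in range(pool.n)]
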