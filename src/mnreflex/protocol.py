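"""Study orchestration: activation levels, noise streams, reflex tables.

One *activation level* is a complete simulated experiment: the whole
pool receives a common mean drive plus band-passed common noise, each
neuron receives its own low-pass independent noise, and an EPSC stimulus
train is delivered. Spike trains are analysed per unit (background DR,
CoV_ISI, inclusion) and reflex amplitudes are estimated from both the
PSF- and PSTH-cusum, yielding a tidy results table.

Random streams are derived deterministically from (global seed, level
index, stream, neuron index), so a study is exactly reproducible and
common noise is shared within a level but redrawn across levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inputs import (
    InputConfig,
    StimulusTrain,
    generate_common_noise_coarse,
    generate_stimulus_train,
    NOISE_SYNTHESIS_DT_MS,
)
from .peristimulus import SIMULATED_WINDOW, estimate_reflex
from .pool import DEFAULT_DT_MS, MNPool, run_pool_kernel
from .spikestats import SpikeTrain, discharge_stats

__all__ = [
    "LEVEL_DRIVES_NA",
    "derive_seed",
    "generate_pool_noise",
    "run_activation_level",
    "run_study",
    "run_pool_compositions",
    "recruitment_fraction",
]

#: the seven mean-drive values (nA) standing in for contraction intensity
LEVEL_DRIVES_NA = {1: 4.0, 2: 6.0, 3: 8.0, 4: 10.0, 5: 12.0, 6: 14.0, 7: 16.0}

#: a unit counts as recruited when it sustains at least the pool's minimum
#: sustained discharge rate; intermittent sub-threshold firing is reported
#: separately via the looser ``firing`` criterion
RECRUITMENT_MIN_RATE_HZ = 7.0
ANY_FIRING_MIN_RATE_HZ = 0.5


def derive_seed(*key: int) -> int:
    """Deterministic 31-bit child seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


def generate_pool_noise(
    n_neurons: int,
    cfg: InputConfig,
    seed: int,
    level: int,
    chunk: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Common and per-neuron independent noise on the coarse synthesis grid."""
    from dataclasses import replace

    from scipy import signal

    from .inputs import independent_noise_sos

    common_cfg = replace(cfg, seed=derive_seed(seed, level, 0))
    common = generate_common_noise_coarse(common_cfg)
    indep = np.empty((n_neurons, common.size))
    target_sd = cfg.independent_noise_sd_nA
    if target_sd == 0.0:
        indep[:] = 0.0
        return common, indep
    sos = independent_noise_sos(cfg)
    # filter neurons in chunks: one sosfiltfilt call per chunk instead of
    # one per neuron
    for lo in range(0, n_neurons, chunk):
        hi = min(lo + chunk, n_neurons)
        white = np.empty((hi - lo, common.size))
        for i in range(lo, hi):
            white[i - lo] = np.random.default_rng(
                derive_seed(seed, level, 1, i)
            ).standard_normal(common.size)
        filtered = signal.sosfiltfilt(sos, white, axis=1)
        sd = filtered.std(axis=1, keepdims=True)
        indep[lo:hi] = filtered * (target_sd / sd)
    return common, indep


def _study_stimuli(n_stimuli: int, seed: int, level: int) -> StimulusTrain:
    return generate_stimulus_train(
        count=n_stimuli,
        start_ms=1000.0,
        seed=derive_seed(seed, level, 2),
    )


def run_activation_level(
    pool: MNPool,
    level: int,
    drive_nA: float | None = None,
    n_stimuli: int = 200,
    seed: int = 0,
    input_cfg: InputConfig | None = None,
    dt_ms: float = DEFAULT_DT_MS,
) -> pd.DataFrame:
    """Simulate one activation level and estimate every unit's reflex.

    Returns a tidy table with one row per (unit, method): discharge
    statistics, inclusion flag, and the PSF/PSTH reflex estimates.
    """
    from dataclasses import replace

    if drive_nA is None:
        drive_nA = LEVEL_DRIVES_NA[level]
    stimuli = _study_stimuli(n_stimuli, seed, level)
    duration_ms = float(stimuli.onsets_ms[-1] + 500.0)
    base = input_cfg or InputConfig()
    cfg = replace(base, mean_drive_nA=drive_nA, duration_ms=duration_ms)
    common, indep = generate_pool_noise(pool.n, cfg, seed, level)
    trains = run_pool_kernel(
        pool, drive_nA, common, indep, duration_ms, stimuli,
        dt_ms=dt_ms, noise_dt_ms=NOISE_SYNTHESIS_DT_MS,
    )
    rows = []
    for mn, times in zip(pool.neurons, trains):
        train = SpikeTrain(times, duration_ms, source="simulated")
        stats = discharge_stats(train, stimuli, mode="simulated")
        overall_rate = 1000.0 * train.n_spikes / duration_ms
        recruited = stats.mean_dr_hz >= RECRUITMENT_MIN_RATE_HZ
        firing = overall_rate >= ANY_FIRING_MIN_RATE_HZ
        for method in ("psf", "psth"):
            if stats.included:
                est = estimate_reflex(
                    train, stimuli, method=method, mode="simulated",
                    window=SIMULATED_WINDOW,
                )
                sig, lat, dur = est.significant, est.latency_ms, est.duration_ms
                amp, norm = est.amplitude, est.normalized_amplitude
            else:
                sig, lat, dur, amp, norm = False, np.nan, np.nan, np.nan, np.nan
            rows.append(
                {
                    "unit": mn.index,
                    "level": level,
                    "drive_nA": drive_nA,
                    "rheobase_nA": mn.target_rheobase_nA,
                    "input_resistance_MOhm": mn.soma_input_resistance_MOhm,
                    "dr_hz": stats.mean_dr_hz,
                    "cov_isi_pct": stats.cov_isi_pct,
                    "recruited": recruited,
                    "firing": firing,
                    "included": stats.included,
                    "method": method,
                    "significant": sig,
                    "latency_ms": lat,
                    "duration_ms": dur,
                    "amplitude": amp,
                    "normalized_amplitude": norm,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    pool: MNPool,
    levels: dict[int, float] | None = None,
    n_stimuli: int = 200,
    seed: int = 0,
    input_cfg: InputConfig | None = None,
) -> pd.DataFrame:
    """Run all activation levels and stack the per-level result tables."""
    levels = levels or LEVEL_DRIVES_NA
    frames = [
        run_activation_level(
            pool, level, drive, n_stimuli=n_stimuli, seed=seed, input_cfg=input_cfg
        )
        for level, drive in sorted(levels.items())
    ]
    return pd.concat(frames, ignore_index=True)


def recruitment_fraction(
    pool: MNPool,
    drive_nA: float,
    duration_s: float = 10.0,
    seed: int = 0,
    level: int = 0,
    min_rate_hz: float = RECRUITMENT_MIN_RATE_HZ,
    transient_ms: float = 1000.0,
    input_cfg: InputConfig | None = None,
) -> tuple[float, int]:
    """Fraction of the pool firing under a noisy drive without stimulation.

    Simulates ``duration_s`` of analysis time per neuron (after a settling
    transient) under the default common plus independent noise and counts
    neurons sustaining at least ``min_rate_hz``. Returns (fraction, count).
    """
    from dataclasses import replace

    duration_ms = transient_ms + duration_s * 1000.0
    base = input_cfg or InputConfig()
    cfg = replace(base, mean_drive_nA=drive_nA, duration_ms=duration_ms)
    common, indep = generate_pool_noise(pool.n, cfg, seed, level)
    trains = run_pool_kernel(
        pool, drive_nA, common, indep, duration_ms, stimuli=None,
        noise_dt_ms=NOISE_SYNTHESIS_DT_MS,
    )
    n_firing = 0
    min_spikes = min_rate_hz * duration_s
    for times in trains:
        if (times >= transient_ms).sum() >= min_spikes:
            n_firing += 1
    return n_firing / pool.n, n_firing


#: exponent scales defining the biased pool compositions compared in the
#: population analysis (smaller scale -> flatter rheobase profile ->
#: proportionally more small, high-resistance neurons)
COMPOSITION_SCALES = (0.5, 0.75, 1.0, 1.25, 1.5)


def run_pool_compositions(
    scales=COMPOSITION_SCALES,
    level: int = 3,
    indices=None,
    n_stimuli: int = 200,
    seed: int = 0,
    constants=None,
) -> dict[float, pd.DataFrame]:
    """Simulate pools of different size composition under identical inputs.

    Every pool shares the same stimulus train, common noise and per-neuron
    independent-noise streams (they depend only on the seed and level), so
    differences in the reflex-amplitude distributions reflect the pool
    composition alone.
    """
    from .params import REFERENCE_NEURON, SizeDistribution
    from .pool import build_pool

    constants = constants or REFERENCE_NEURON
    out: dict[float, pd.DataFrame] = {}
    for scale in scales:
        pool = build_pool(
            distribution=SizeDistribution().biased(scale),
            constants=constants,
            indices=indices,
        )
        out[scale] = run_activation_level(
            pool, level, n_stimuli=n_stimuli, seed=seed
        )
    return out
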