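"""Fixed-step integrators for the two-compartment pulse-gating neuron.

The soma voltage obeys

    C_s dVs/dt = I(t) - g_Na m^3 h (Vs - E_Na) - (g_Kf n^4 + g_Ks q^2)(Vs - E_K)
                 - g_ls (Vs - E_l) - g_c (Vs - Vd)

with a passive dendrite ``C_d dVd/dt = -g_ld (Vd - E_l) - g_c (Vd - Vs)``.
Each gating variable relaxes with a constant rate that is switched by a
fixed-duration pulse triggered when Vs crosses the gate threshold from
below; because the rates are piecewise constant, the gate updates are
exact exponential relaxations with precomputed per-step factors, and the
voltage updates use exponential Euler. With dt = 0.05 ms the stimulus
rise time (1 ms) is resolved by 20 steps.

Pool neurons scale the reference neuron's conductances by ``sigma_i``
and its capacitances by an independent factor. In the reference frame
(conductances unscaled, current divided by ``sigma_i``) this leaves an
effective capacitance multiplier ``c_div_i = c_factor_i / sigma_i``;
uniform scaled copies correspond to ``c_div = 1``.

Band-limited noise (< 100 Hz) enters on a coarse grid (default 1 ms) and
is linearly interpolated to the integration grid inside the kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# layout of the packed parameter vector
P_CS, P_CD, P_GLS, P_GLD, P_GC, P_GNA, P_GKF, P_GKS = range(8)
P_EL, P_ENA, P_EK = 8, 9, 10
P_AM, P_BM, P_AH, P_BH, P_AN, P_BN, P_AQ, P_BQ = range(11, 19)
P_VGATE, P_PULSE, P_TRIG_LOCK, P_VDETECT, P_DET_LOCK = range(19, 24)
N_PARAMS = 24


def pack_params(c) -> np.ndarray:
    """Pack NeuronConstants into the kernel parameter vector."""
    p = np.empty(N_PARAMS)
    p[P_CS], p[P_CD] = c.c_soma_nF, c.c_dend_nF
    p[P_GLS], p[P_GLD], p[P_GC] = c.g_leak_soma_uS, c.g_leak_dend_uS, c.g_coupling_uS
    p[P_GNA], p[P_GKF], p[P_GKS] = c.g_na_uS, c.g_kf_uS, c.g_ks_uS
    p[P_EL], p[P_ENA], p[P_EK] = c.e_leak_mV, c.e_na_mV, c.e_k_mV
    p[P_AM], p[P_BM] = c.alpha_m, c.beta_m
    p[P_AH], p[P_BH] = c.alpha_h, c.beta_h
    p[P_AN], p[P_BN] = c.alpha_n, c.beta_n
    p[P_AQ], p[P_BQ] = c.alpha_q, c.beta_q
    p[P_VGATE], p[P_PULSE] = c.v_gate_mV, c.pulse_ms
    p[P_TRIG_LOCK] = c.trigger_lockout_ms
    p[P_VDETECT], p[P_DET_LOCK] = c.v_detect_mV, c.detect_lockout_ms
    return p


@njit(cache=True)
def integrate_pool(
    dt: float,
    n_steps: int,
    p: np.ndarray,
    sigma: np.ndarray,
    c_div: np.ndarray,
    i_mean: float,
    common: np.ndarray,
    indep: np.ndarray,
    noise_stride: int,
    epsc: np.ndarray,
    stim_steps: np.ndarray,
    max_spikes: int,
):
    """Integrate the whole pool; returns (spike counts, spike times, diverged)."""
    n_neurons = sigma.size
    e_l, e_na, e_k = p[P_EL], p[P_ENA], p[P_EK]
    g_ls, g_ld, g_c = p[P_GLS], p[P_GLD], p[P_GC]
    g_na, g_kf, g_ks = p[P_GNA], p[P_GKF], p[P_GKS]
    c_s, c_d = p[P_CS], p[P_CD]
    v_gate, pulse_ms = p[P_VGATE], p[P_PULSE]
    trig_lock, v_detect, det_lock = p[P_TRIG_LOCK], p[P_VDETECT], p[P_DET_LOCK]

    # exact per-step relaxation factors for the piecewise-constant rates
    em_on, em_off = np.exp(-p[P_AM] * dt), np.exp(-p[P_BM] * dt)
    eh_on, eh_off = np.exp(-p[P_BH] * dt), np.exp(-p[P_AH] * dt)
    en_on, en_off = np.exp(-p[P_AN] * dt), np.exp(-p[P_BN] * dt)
    eq_on, eq_off = np.exp(-p[P_AQ] * dt), np.exp(-p[P_BQ] * dt)

    g_dend_tot = g_ld + g_c
    # per-neuron capacitance divisor: effective reference-frame capacitance
    # is c * c_div[i] (uniform copies have c_div = 1)
    ed = np.exp(-dt * g_dend_tot / (c_d * c_div))

    vs = np.full(n_neurons, e_l)
    vd = np.full(n_neurons, e_l)
    m = np.zeros(n_neurons)
    h = np.ones(n_neurons)
    ng = np.zeros(n_neurons)
    q = np.zeros(n_neurons)
    pulse_end = np.full(n_neurons, -1.0)
    trig_ok = np.zeros(n_neurons)
    last_det = np.full(n_neurons, -1e9)
    alive = np.ones(n_neurons, dtype=np.bool_)

    counts = np.zeros(n_neurons, dtype=np.int64)
    times = np.zeros((n_neurons, max_spikes))
    n_epsc = epsc.size
    n_stim = stim_steps.size
    s_ptr = 0

    for step in range(n_steps):
        t = step * dt
        # stimulus current, shared by the pool
        while s_ptr < n_stim and step >= stim_steps[s_ptr] + n_epsc:
            s_ptr += 1
        i_stim = 0.0
        if s_ptr < n_stim and step >= stim_steps[s_ptr]:
            i_stim = epsc[step - stim_steps[s_ptr]]
        # common noise, linearly interpolated from the coarse grid
        j = step // noise_stride
        frac = (step - j * noise_stride) / noise_stride
        c_noise = common[j] + (common[j + 1] - common[j]) * frac
        i_shared = i_mean + c_noise + i_stim

        for i in range(n_neurons):
            if not alive[i]:
                continue
            ind = indep[i, j] + (indep[i, j + 1] - indep[i, j]) * frac
            cur = (i_shared + ind) / sigma[i]

            in_pulse = t < pulse_end[i]
            if in_pulse:
                m[i] = 1.0 + (m[i] - 1.0) * em_on
                h[i] = h[i] * eh_on
                ng[i] = 1.0 + (ng[i] - 1.0) * en_on
                q[i] = 1.0 + (q[i] - 1.0) * eq_on
            else:
                m[i] = m[i] * em_off
                h[i] = 1.0 + (h[i] - 1.0) * eh_off
                ng[i] = ng[i] * en_off
                q[i] = q[i] * eq_off

            # spike conductances live on the soma and scale with its
            # capacitance; AHP and passive conductances scale with size
            gna = g_na * c_div[i] * m[i] * m[i] * m[i] * h[i]
            n2 = ng[i] * ng[i]
            gk = g_kf * c_div[i] * n2 * n2 + g_ks * q[i] * q[i]
            g_tot = gna + gk + g_ls + g_c
            b = gna * e_na + gk * e_k + g_ls * e_l + g_c * vd[i] + cur
            v_inf = b / g_tot
            vs_old = vs[i]
            vs[i] = v_inf + (vs_old - v_inf) * np.exp(
                -dt * g_tot / (c_s * c_div[i])
            )

            vd_inf = (g_ld * e_l + g_c * vs_old) / g_dend_tot
            vd[i] = vd_inf + (vd[i] - vd_inf) * ed[i]

            if not np.isfinite(vs[i]):
                alive[i] = False
                continue

            if vs[i] >= v_gate and vs_old < v_gate and t >= trig_ok[i]:
                pulse_end[i] = t + pulse_ms
                trig_ok[i] = t + trig_lock

            if (
                vs[i] >= v_detect
                and vs_old < v_detect
                and t - last_det[i] >= det_lock
            ):
                last_det[i] = t
                if counts[i] < max_spikes:
                    times[i, counts[i]] = t
                counts[i] += 1

    return counts, times, ~alive


@njit(cache=True)
def integrate_single(
    dt: float,
    p: np.ndarray,
    sigma: float,
    c_div: float,
    current: np.ndarray,
    max_spikes: int,
):
    """Integrate one neuron under a full-resolution current trace.

    Returns (vs, vd, gates (4 x n), spike count, spike times, diverged).
    The step math mirrors ``integrate_pool`` exactly (kept in sync by a
    dedicated equivalence test).
    """
    n_steps = current.size
    e_l, e_na, e_k = p[P_EL], p[P_ENA], p[P_EK]
    g_ls, g_ld, g_c = p[P_GLS], p[P_GLD], p[P_GC]
    g_na, g_kf, g_ks = p[P_GNA], p[P_GKF], p[P_GKS]
    c_s, c_d = p[P_CS], p[P_CD]
    v_gate, pulse_ms = p[P_VGATE], p[P_PULSE]
    trig_lock, v_detect, det_lock = p[P_TRIG_LOCK], p[P_VDETECT], p[P_DET_LOCK]

    em_on, em_off = np.exp(-p[P_AM] * dt), np.exp(-p[P_BM] * dt)
    eh_on, eh_off = np.exp(-p[P_BH] * dt), np.exp(-p[P_AH] * dt)
    en_on, en_off = np.exp(-p[P_AN] * dt), np.exp(-p[P_BN] * dt)
    eq_on, eq_off = np.exp(-p[P_AQ] * dt), np.exp(-p[P_BQ] * dt)
    g_dend_tot = g_ld + g_c
    ed = np.exp(-dt * g_dend_tot / (c_d * c_div))

    vs_tr = np.empty(n_steps)
    vd_tr = np.empty(n_steps)
    gates = np.empty((4, n_steps))
    times = np.zeros(max_spikes)
    count = 0
    diverged = False

    vs, vd = e_l, e_l
    m, h, ng, q = 0.0, 1.0, 0.0, 0.0
    pulse_end, trig_ok, last_det = -1.0, 0.0, -1e9

    for step in range(n_steps):
        t = step * dt
        cur = current[step] / sigma

        if t < pulse_end:
            m = 1.0 + (m - 1.0) * em_on
            h = h * eh_on
            ng = 1.0 + (ng - 1.0) * en_on
            q = 1.0 + (q - 1.0) * eq_on
        else:
            m = m * em_off
            h = 1.0 + (h - 1.0) * eh_off
            ng = ng * en_off
            q = q * eq_off

        gna = g_na * c_div * m * m * m * h
        n2 = ng * ng
        gk = g_kf * c_div * n2 * n2 + g_ks * q * q
        g_tot = gna + gk + g_ls + g_c
        b = gna * e_na + gk * e_k + g_ls * e_l + g_c * vd + cur
        v_inf = b / g_tot
        vs_old = vs
        vs = v_inf + (vs_old - v_inf) * np.exp(-dt * g_tot / (c_s * c_div))

        vd_inf = (g_ld * e_l + g_c * vs_old) / g_dend_tot
        vd = vd_inf + (vd - vd_inf) * ed

        if not np.isfinite(vs):
            diverged = True
            vs_tr[step:] = np.nan
            vd_tr[step:] = np.nan
            gates[:, step:] = np.nan
            break

        if vs >= v_gate and vs_old < v_gate and t >= trig_ok:
            pulse_end = t + pulse_ms
            trig_ok = t + trig_lock

        if vs >= v_detect and vs_old < v_detect and t - last_det >= det_lock:
            last_det = t
            if count < max_spikes:
                times[count] = t
            count += 1

        vs_tr[step] = vs
        vd_tr[step] = vd
        gates[0, step] = m
        gates[1, step] = h
        gates[2, step] = ng
        gates[3, step] = q

    return vs_tr, vd_tr, gates, count, times, diverged
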