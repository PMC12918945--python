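"""Reference-neuron constants and pool size-distribution parameters.

The motor neuron model is a two-compartment conductance-based model in
the pulse-gating family: an excitable soma carrying Na+, fast K+ and
slow K+ (AHP) currents whose four gating variables (m, h, n, q) relax
with constant rates that are switched by a fixed-duration suprathreshold
pulse, electrotonically coupled to a passive dendrite compartment. All
pool neurons are uniformly scaled copies of one reference neuron: every
conductance and capacitance of neuron i is multiplied by a size factor,
so input resistance is exactly exponential across the pool and each
neuron's dynamics equal the reference dynamics under a current divided
by its size factor.

Units: mV, ms, nA, uS, nF (so g/C is in 1/ms and R = 1/g in MOhm).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["NeuronConstants", "SizeDistribution", "REFERENCE_NEURON"]


@dataclass(frozen=True)
class NeuronConstants:
    """Electrical constants of the reference (unit-size) motor neuron."""

    # passive structure
    c_soma_nF: float = 1.0
    c_dend_nF: float = 3.0
    g_leak_soma_uS: float = 0.040
    g_leak_dend_uS: float = 0.060
    g_coupling_uS: float = 0.100
    e_leak_mV: float = -70.0

    # active conductances (soma)
    g_na_uS: float = 200.0
    g_kf_uS: float = 25.0
    g_ks_uS: float = 2.0
    e_na_mV: float = 50.0
    e_k_mV: float = -80.0

    # pulse-gating kinetics (1/ms); the pulse switches each gate between
    # its "on" and "off" rate
    alpha_m: float = 22.0
    beta_m: float = 13.0
    alpha_h: float = 0.5
    beta_h: float = 4.0
    alpha_n: float = 1.5
    beta_n: float = 0.10
    alpha_q: float = 4.0
    beta_q: float = 0.030

    # spike machinery
    v_gate_mV: float = -62.0       # pulse-trigger threshold
    pulse_ms: float = 0.6          # gating-pulse duration
    trigger_lockout_ms: float = 2.0
    v_detect_mV: float = 0.0       # reported spike = upward crossing of 0 mV
    detect_lockout_ms: float = 1.0

    @property
    def input_resistance_MOhm(self) -> float:
        """Steady-state soma input resistance of the passive structure."""
        g_d = self.g_coupling_uS * self.g_leak_dend_uS / (
            self.g_coupling_uS + self.g_leak_dend_uS
        )
        return 1.0 / (self.g_leak_soma_uS + g_d)

    def as_dict(self) -> dict:
        return asdict(self)


REFERENCE_NEURON = NeuronConstants()


@dataclass(frozen=True)
class SizeDistribution:
    """Exponential rheobase (hence input-resistance) profile of the pool.

    Neuron i (1-based) has target rheobase
    ``rho(i) = rho_low * exp(theta * (i - i_low))`` with ``theta`` set so
    that ``rho(i_high) = rho_high``. The two anchors implement the
    recruitment calibration: with the default noisy drive, about 44.5% of
    a 200-neuron pool fires at a 4 nA mean drive (anchor at index 89) and
    about 98.5% at 16 nA (anchor at index 197). Recruitment means
    sustained firing at or above the pool's minimum sustained rate (~7 Hz);
    band-limited noise lets neurons with rheobase near or slightly above
    the mean drive reach that rate.

    ``exponent_scale`` generates biased pool compositions for population
    comparisons: the exponent theta is multiplied by the scale while the
    rheobase of neuron 1 is held fixed, so scales < 1 flatten the profile
    (proportionally more small, high-resistance neurons) and scales > 1
    steepen it (proportionally more large neurons).
    """

    anchor_low_index: int = 89
    anchor_low_rheobase_nA: float = 4.64
    anchor_high_index: int = 197
    anchor_high_rheobase_nA: float = 19.50
    exponent_scale: float = 1.0
    #: capacitances scale as size**capacitance_exponent: 0 = shared
    #: capacitance across the pool, 1 = uniform scaled copies
    capacitance_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.anchor_low_rheobase_nA <= 0 or self.anchor_high_rheobase_nA <= 0:
            raise ValueError("anchor rheobases must be positive")
        if self.anchor_high_index <= self.anchor_low_index:
            raise ValueError("anchor indices must be increasing")
        if self.anchor_high_rheobase_nA <= self.anchor_low_rheobase_nA:
            raise ValueError("rheobase must increase with index")
        if self.exponent_scale <= 0:
            raise ValueError("exponent_scale must be positive")

    @property
    def theta(self) -> float:
        import math

        return (
            math.log(self.anchor_high_rheobase_nA / self.anchor_low_rheobase_nA)
            / (self.anchor_high_index - self.anchor_low_index)
        )

    def rheobase_nA(self, index: int) -> float:
        """Target rheobase of 1-based neuron ``index``."""
        import math

        base = self.anchor_low_rheobase_nA
        theta = self.theta
        # rheobase of neuron 1 under the unbiased profile is the fixed point
        rho_1 = base * math.exp(theta * (1 - self.anchor_low_index))
        return rho_1 * math.exp(self.exponent_scale * theta * (index - 1))

    def biased(self, exponent_scale: float) -> "SizeDistribution":
        from dataclasses import replace

        return replace(self, exponent_scale=exponent_scale)
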