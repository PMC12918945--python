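"""Pool construction, membrane dynamics, rheobase and f-I properties."""

from dataclasses import replace

import numpy as np
import pytest

from mnreflex.inputs import CurrentTrace
from mnreflex.params import REFERENCE_NEURON, SizeDistribution
from mnreflex.pool import (
    MNParameters,
    build_pool,
    f_i_curve,
    reference_rheobase,
    rheobase,
    run_pool_kernel,
    simulate_mn,
)


class TestBuildPool:
    def test_default_pool_size_and_ordering(self, default_pool):
        assert default_pool.n == 200
        r_in = default_pool.input_resistances_MOhm()
        assert np.all(np.diff(r_in) < 0)  # strictly decreasing with index

    def test_input_resistance_profile_is_exponential(self, default_pool):
        r_in = default_pool.input_resistances_MOhm()
        log_ratio = np.diff(np.log(r_in))
        np.testing.assert_allclose(log_ratio, log_ratio[0], rtol=1e-9)

    def test_single_neuron_pool(self):
        pool = build_pool(n_mns=1)
        assert pool.n == 1

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            SizeDistribution(anchor_low_rheobase_nA=-1.0)
        with pytest.raises(ValueError):
            SizeDistribution(anchor_low_rheobase_nA=5.0, anchor_high_rheobase_nA=4.0)

    def test_yaml_roundtrip(self, small_pool, tmp_path):
        import yaml

        path = tmp_path / "pool.yaml"
        small_pool.to_yaml(path)
        doc = yaml.safe_load(path.read_text())
        assert len(doc["neurons"]) == 50
        assert doc["neurons"][0]["soma_input_resistance_MOhm"] > doc["neurons"][-1][
            "soma_input_resistance_MOhm"
        ]


class TestSimulateMN:
    def test_zero_input_relaxes_to_rest(self, reference_neuron):
        trace = simulate_mn(reference_neuron, CurrentTrace(0.05, np.zeros(20_000)))
        assert trace.spike_times_ms.size == 0
        assert trace.soma_mV[-1] == pytest.approx(-70.0, abs=0.1)

    def test_supra_rheobase_tonic_firing_is_regular(
        self, reference_neuron, ref_rheobase
    ):
        current = np.full(100_000, 2.0 * ref_rheobase)  # 5 s
        trace = simulate_mn(reference_neuron, CurrentTrace(0.05, current))
        spikes = trace.spike_times_ms
        spikes = spikes[spikes > 1000.0]
        isis = np.diff(spikes)
        assert isis.size > 10
        assert 100.0 * isis.std() / isis.mean() < 1.0  # noiseless CoV < 1%

    def test_determinism_bit_identical(self, reference_neuron, ref_rheobase):
        current = np.full(40_000, 3.0 * ref_rheobase)
        a = simulate_mn(reference_neuron, CurrentTrace(0.05, current))
        b = simulate_mn(reference_neuron, CurrentTrace(0.05, current))
        np.testing.assert_array_equal(a.spike_times_ms, b.spike_times_ms)
        np.testing.assert_array_equal(a.soma_mV, b.soma_mV)

    def test_spikes_cross_detection_threshold(self, reference_neuron, ref_rheobase):
        current = np.full(40_000, 2.0 * ref_rheobase)
        trace = simulate_mn(reference_neuron, CurrentTrace(0.05, current))
        assert trace.spike_times_ms.size > 0
        # soma voltage overshoots the 0 mV detection level at each spike
        assert trace.soma_mV.max() > 0.0

    def test_coarse_dt_rejected(self, reference_neuron):
        with pytest.raises(ValueError):
            simulate_mn(reference_neuron, CurrentTrace(0.2, np.zeros(100)))

    def test_trace_csv_export(self, reference_neuron, ref_rheobase, tmp_path):
        import pandas as pd

        current = np.full(20_000, 2.0 * ref_rheobase)
        trace = simulate_mn(reference_neuron, CurrentTrace(0.05, current))
        vpath, spath = tmp_path / "v.csv", tmp_path / "spikes.csv"
        trace.to_csv(vpath, spath)
        v = pd.read_csv(vpath)
        assert list(v.columns) == ["time_ms", "soma_mV", "dendrite_mV"]
        assert len(v) == 20_000
        spikes = pd.read_csv(spath)
        np.testing.assert_allclose(
            spikes["spike_time_ms"].to_numpy(), trace.spike_times_ms
        )


class TestRheobase:
    def test_doubled_leak_increases_rheobase(self):
        base = rheobase(REFERENCE_NEURON)
        leaky = replace(
            REFERENCE_NEURON, g_leak_soma_uS=2 * REFERENCE_NEURON.g_leak_soma_uS
        )
        assert rheobase(leaky) > base

    def test_scaling_law_against_bisection_oracle(self, default_pool, ref_rheobase):
        # brute-force bisection on sampled neurons must match sigma * rho_ref
        for idx in (0, 49, 99, 149, 199):
            mn = default_pool.neurons[idx]
            measured = rheobase(mn, tolerance_nA=0.02)
            assert measured == pytest.approx(
                mn.size_factor * ref_rheobase, rel=0.03
            )

    def test_rheobase_increases_with_index(self, default_pool):
        measured = [
            rheobase(default_pool.neurons[i], tolerance_nA=0.02)
            for i in range(0, 200, 40)
        ]
        assert np.all(np.diff(measured) > 0)

    def test_smallest_neuron_recruited_at_level_one(self, default_pool):
        assert rheobase(default_pool.neurons[0], tolerance_nA=0.02) < 4.0


class TestFICurve:
    def test_below_rheobase_silent(self, reference_neuron, ref_rheobase):
        curve = f_i_curve(
            reference_neuron, [0.5 * ref_rheobase], sim_s=3.0, transient_s=1.0
        )
        assert curve[0][1] == 0.0

    def test_monotone_non_decreasing(self, reference_neuron, ref_rheobase):
        currents = ref_rheobase * np.array([1.1, 2.0, 4.0, 6.0, 9.0, 12.0])
        curve = f_i_curve(reference_neuron, currents, sim_s=5.0)
        rates = [f for _, f in curve]
        assert np.all(np.diff(rates) >= 0)

    def test_initial_slope_steeper_than_midrange(
        self, reference_neuron, ref_rheobase
    ):
        currents = ref_rheobase * np.array([1.02, 1.5, 4.0, 6.0])
        curve = f_i_curve(reference_neuron, currents, sim_s=5.0)
        (i0, f0), (i1, f1), (i2, f2), (i3, f3) = curve
        first = (f1 - f0) / (i1 - i0)
        middle = (f3 - f2) / (i3 - i2)
        assert first > middle

    def test_unsorted_currents_rejected(self, reference_neuron):
        with pytest.raises(ValueError):
            f_i_curve(reference_neuron, [2.0, 1.0])


class TestKernelConsistency:
    def test_pool_and_single_kernels_agree(self, small_pool):
        # same physical input fed through both code paths
        rng = np.random.default_rng(0)
        dur = 4000.0
        n_coarse = int(dur) + 2
        common = rng.normal(0, 0.5, n_coarse)
        indep = rng.normal(0, 0.25, (small_pool.n, n_coarse))
        trains = run_pool_kernel(small_pool, 8.0, common, indep, dur)
        n_steps = int(dur / 0.05)
        t_fine = np.arange(n_steps) * 0.05
        t_coarse = np.arange(n_coarse) * 1.0
        for idx in (0, 25, 49):
            mn = small_pool.neurons[idx]
            current = 8.0 + np.interp(t_fine, t_coarse, common) + np.interp(
                t_fine, t_coarse, indep[idx]
            )
            trace = simulate_mn(mn, CurrentTrace(0.05, current))
            a, b = trains[idx], trace.spike_times_ms
            assert a.size == b.size
            if a.size:
                np.testing.assert_allclose(a, b, atol=0.1)

    def test_size_principle_recruitment_order_on_ramp(self, small_pool):
        # slow noiseless ramp: recruitment order must equal index order
        dur = 30_000.0
        n_coarse = int(dur) + 2
        ramp = np.linspace(0.0, 25.0, n_coarse)
        indep = np.zeros((small_pool.n, n_coarse))
        trains = run_pool_kernel(small_pool, 0.0, ramp, indep, dur)
        first_spikes = [t[0] if t.size else np.inf for t in trains]
        finite = [t for t in first_spikes if np.isfinite(t)]
        assert len(finite) == small_pool.n  # ramp exceeds every rheobase
        assert np.all(np.diff(first_spikes) > 0)
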