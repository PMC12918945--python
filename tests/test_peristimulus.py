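"""PSTH/PSF construction, cusum algebra, error box, reflex detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnreflex.inputs import StimulusTrain, generate_stimulus_train
from mnreflex.peristimulus import (
    EXPERIMENTAL_WINDOW,
    SIMULATED_WINDOW,
    PeristimulusData,
    Window,
    build_psf,
    build_psth,
    cusum,
    detect_reflex_auto,
    error_box,
    estimate_reflex,
)
from mnreflex.spikestats import SpikeTrain
from mnreflex.surrogate import SurrogateConfig, inject_reflex, renewal_train


@pytest.fixture()
def stimuli():
    return generate_stimulus_train(count=100, seed=5)


def _spike_after_every_stimulus(stimuli, latency=5.0, duration=150_000.0):
    times = np.sort(stimuli.onsets_ms + latency)
    return SpikeTrain(times, duration, source="surrogate")


class TestBuildPsth:
    def test_single_spike_per_stimulus(self, stimuli):
        train = _spike_after_every_stimulus(stimuli)
        data = build_psth(train, stimuli, window=SIMULATED_WINDOW, bin_ms=1.0)
        k = data.n_pre_bins + 5  # bin [5, 6) ms
        assert data.values[k] == stimuli.count
        # remaining mass only from neighbouring stimuli's spikes in-window
        assert data.values.sum() >= stimuli.count

    def test_empty_train(self, stimuli):
        data = build_psth(SpikeTrain(np.empty(0), 1000.0), stimuli)
        assert np.all(data.values == 0.0)

    def test_total_mass_counts_peristimulus_spikes(self, stimuli, background_train):
        data = build_psth(background_train, stimuli, window=EXPERIMENTAL_WINDOW)
        t = background_train.times_ms
        expected = sum(
            int(((t >= o - 200.0) & (t < o + 100.0)).sum())
            for o in stimuli.onsets_ms
        )
        assert data.values.sum() == expected

    def test_requires_stimuli(self):
        with pytest.raises(ValueError):
            build_psth(SpikeTrain(np.empty(0), 10.0), StimulusTrain(np.empty(0)))


class TestBuildPsf:
    def test_periodic_train_contributes_its_rate(self, stimuli, periodic_train_10hz):
        data = build_psf(periodic_train_10hz, stimuli, window=SIMULATED_WINDOW)
        nonzero = data.values[data.values > 0]
        counts = data.counts[data.values > 0]
        np.testing.assert_allclose(nonzero / counts, 10.0, rtol=1e-9)

    def test_empty_train(self, stimuli):
        data = build_psf(SpikeTrain(np.empty(0), 1000.0), stimuli)
        assert np.all(data.values == 0.0)

    def test_halved_isi_doubles_post_stimulus_rates(self):
        # deterministic surrogate: background 10 Hz; after each stimulus the
        # next spike comes at half the ISI -> its instantaneous rate doubles
        stim = generate_stimulus_train(count=50, isi_sd_ms=0.0, seed=0)
        times = np.concatenate(
            [o + np.array([-425.0, -325.0, -225.0, -125.0, -25.0, 25.0,
                           125.0, 225.0, 325.0, 425.0])
             for o in stim.onsets_ms]
        )
        times = np.unique(times)
        train = SpikeTrain(times, 52_000.0, source="surrogate")
        data = build_psf(train, stim, window=EXPERIMENTAL_WINDOW)
        post = slice(data.n_pre_bins, None)
        post_rates = data.values[post][data.counts[post] > 0]
        post_counts = data.counts[post][data.counts[post] > 0]
        assert (post_rates / post_counts).max() == pytest.approx(20.0, rel=1e-9)


class TestCusum:
    def test_flat_histogram_gives_zero_cusum(self, stimuli):
        edges = np.arange(-200.0, 101.0, 1.0)
        data = PeristimulusData(
            "psth", edges, np.full(300, 3.0), EXPERIMENTAL_WINDOW, stimuli.count
        )
        c = cusum(data)
        np.testing.assert_allclose(c.values, 0.0, atol=1e-9)

    def test_single_elevated_bin_makes_step(self, stimuli):
        edges = np.arange(-200.0, 101.0, 1.0)
        vals = np.zeros(300)
        vals[210] = 5.0  # 10 ms post-stimulus
        data = PeristimulusData("psth", edges, vals, EXPERIMENTAL_WINDOW, 100)
        c = cusum(data)
        assert c.values[209] == pytest.approx(0.0)
        assert c.values[-1] == pytest.approx(5.0, abs=0.1)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pre_stimulus_terminal_value_exactly_zero(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.arange(-50.0, 26.0, 1.0)
        vals = rng.poisson(3.0, size=75).astype(float)
        data = PeristimulusData("psth", edges, vals, Window(50.0, 25.0), 10)
        c = cusum(data)
        assert c.values[data.n_pre_bins - 1] == pytest.approx(0.0, abs=1e-9)

    def test_psf_cusum_pre_terminal_zero(self, stimuli, background_train):
        data = build_psf(background_train, stimuli, window=EXPERIMENTAL_WINDOW)
        c = cusum(data)
        assert c.values[data.n_pre_bins - 1] == pytest.approx(0.0, abs=1e-6)


class TestErrorBox:
    def test_zero_prestimulus_cusum_any_deflection_significant(self):
        edges = np.arange(-20.0, 11.0, 1.0)
        vals = np.zeros(30)
        vals[25] = 2.0  # single post-stimulus event, silent baseline
        data = PeristimulusData("psth", edges, vals, Window(20.0, 10.0), 10)
        c = cusum(data)
        assert error_box(c) == pytest.approx(0.0, abs=1e-12)
        assert detect_reflex_auto(c, mode="experimental").significant

    def test_strict_exceedance(self):
        # post-stimulus peak exactly below the box must not be significant
        edges = np.arange(-4.0, 3.0, 1.0)
        vals = np.array([0.0, 0.4, 0.0, 0.0, 0.2, 0.19, 0.0])
        data = PeristimulusData("psth", edges, vals, Window(4.0, 3.0), 10)
        c = cusum(data)
        est = detect_reflex_auto(c, mode="experimental")
        assert not est.significant

    def test_flat_cusum_no_crash(self, stimuli):
        edges = np.arange(-200.0, 101.0, 1.0)
        data = PeristimulusData(
            "psth", edges, np.full(300, 2.0), EXPERIMENTAL_WINDOW, 100
        )
        est = detect_reflex_auto(cusum(data), mode="experimental")
        assert not est.significant
        assert est.normalized_amplitude == 0.0


class TestDetectReflexAuto:
    def test_certain_extra_spike_amplitude_one(self, stimuli):
        train = _spike_after_every_stimulus(stimuli)
        est = estimate_reflex(train, stimuli, method="psth", mode="experimental")
        assert est.significant
        assert est.normalized_amplitude == pytest.approx(1.0, abs=0.05)
        assert abs(est.latency_ms - 5.0) <= 1.0

    def test_half_probability_amplitude(self):
        cfg = SurrogateConfig(
            dr_hz=10.0, cov_isi_pct=15.0, duration_ms=220_000.0,
            reflex_mode="extra-spike", reflex_probability=0.5,
            reflex_latency_ms=5.0, seed=12,
        )
        stim = generate_stimulus_train(count=200, seed=13)
        train, record = inject_reflex(renewal_train(cfg), stim, cfg)
        est = estimate_reflex(train, stim, method="psth", mode="experimental")
        p_hat = record.n_injected / stim.count
        se = 3 * np.sqrt(0.25 / stim.count)
        assert est.significant
        assert abs(est.normalized_amplitude - p_hat) <= se + 0.03

    def test_simulated_mode_onset_limit(self, stimuli):
        # a response starting 30 ms post-stimulus is outside the simulated
        # no-conduction-delay window and must not be picked as onset
        train = _spike_after_every_stimulus(stimuli, latency=30.0)
        est = estimate_reflex(train, stimuli, method="psth", mode="simulated")
        assert not (est.significant and est.onset_ms <= 15.0 and est.amplitude > 50)
        est_exp = estimate_reflex(train, stimuli, method="psth", mode="experimental")
        assert est_exp.normalized_amplitude == pytest.approx(1.0, abs=0.05)

    def test_psf_and_psth_share_onset_for_added_discharge(self, stimuli):
        cfg = SurrogateConfig(
            dr_hz=10.0, cov_isi_pct=15.0, duration_ms=220_000.0,
            reflex_mode="extra-spike", reflex_probability=1.0,
            reflex_latency_ms=5.0, seed=4,
        )
        stim = generate_stimulus_train(count=200, seed=5)
        train, _ = inject_reflex(renewal_train(cfg), stim, cfg)
        psf_est = estimate_reflex(train, stim, method="psf", mode="experimental")
        psth_est = estimate_reflex(train, stim, method="psth", mode="experimental")
        assert abs(psf_est.onset_ms - psth_est.onset_ms) <= 1.0
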