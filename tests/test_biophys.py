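"""Neuron/synapse primitives and the network integrator."""

import numpy as np
import pytest

from sleepwake import (
    IntegrationError,
    KINETICS,
    NeuronParams,
    ParameterError,
    PopulationSpec,
    StimProtocol,
    SynapseKinetics,
    build_circuit,
    synaptic_conductance_waveform,
)
from sleepwake import biophys
from sleepwake.biophys import simulate_single_neuron, waveform_peak_time


class TestParams:
    def test_reversal_ordering_enforced(self):
        with pytest.raises(ParameterError):
            NeuronParams(e_na=-80.0)  # E_Na must exceed E_leak
        with pytest.raises(ParameterError):
            NeuronParams(e_k=-50.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ParameterError):
            NeuronParams(g_na=-1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            NeuronParams(noise_amplitude=-0.1)

    def test_synapse_time_constants(self):
        with pytest.raises(ParameterError):
            SynapseKinetics("fast_excitatory", 5.0, 1.0, 0.0, 0.1)  # decay < rise
        with pytest.raises(ParameterError):
            SynapseKinetics("fast_excitatory", 0.0, 5.0, 0.0, 0.1)  # rise = 0

    def test_slow_hcrt_must_be_slow(self):
        with pytest.raises(ParameterError):
            SynapseKinetics("slow_hcrt", 100.0, 5000.0, 0.0, 0.1)

    def test_fast_kinds_must_be_fast(self):
        with pytest.raises(ParameterError):
            SynapseKinetics("fast_gabaa", 1.0, 100.0, -80.0, 0.1)

    def test_inhibitory_reversal_below_rest(self):
        with pytest.raises(ParameterError):
            SynapseKinetics("fast_gabaa", 0.5, 10.0, -40.0, 0.1)

    def test_population_invariants(self):
        with pytest.raises(ParameterError):
            PopulationSpec("X", 0)
        with pytest.raises(ParameterError):
            PopulationSpec("X", 5, p_inter=1.5)


class TestWaveform:
    def test_no_spikes_is_zero(self):
        kin = KINETICS["fast_excitatory"]
        t = np.arange(0.0, 100.0, 0.1)
        assert not synaptic_conductance_waveform(kin, [], t).any()

    def test_peak_location_and_height(self):
        """Single spike: peak at delay + (τr·τd/(τd−τr))·ln(τd/τr), height gmax."""
        kin = SynapseKinetics("fast_excitatory", 1.0, 5.0, 0.0, 0.25, delay_ms=2.0)
        t = np.arange(0.0, 60.0, 0.001)
        g = synaptic_conductance_waveform(kin, [10.0], t)
        tp_expected = (1.0 * 5.0 / 4.0) * np.log(5.0)  # 2.0118 ms
        assert t[np.argmax(g)] == pytest.approx(10.0 + 2.0 + tp_expected, abs=0.01)
        assert g.max() == pytest.approx(0.25, rel=1e-6)
        assert waveform_peak_time(kin) == pytest.approx(tp_expected, rel=1e-12)

    def test_matches_independent_closed_form(self):
        """Relative error < 1e-6 against a directly coded double exponential."""
        kin = SynapseKinetics("slow_histamine", 50.0, 2000.0, 0.0, 0.7, delay_ms=1.0)
        t = np.linspace(0.0, 20_000.0, 2001)
        g = synaptic_conductance_waveform(kin, [500.0, 800.0], t)
        tp = (50.0 * 2000.0 / 1950.0) * np.log(40.0)
        norm = 1.0 / (np.exp(-tp / 2000.0) - np.exp(-tp / 50.0))
        ref = np.zeros_like(t)
        for ts in (501.0, 801.0):
            dt = t - ts
            on = dt > 0
            ref[on] += 0.7 * norm * (np.exp(-dt[on] / 2000.0) - np.exp(-dt[on] / 50.0))
        nz = ref > 1e-12
        assert np.max(np.abs(g[nz] - ref[nz]) / ref[nz]) < 1e-6

    def test_slow_hcrt_minute_scale_persistence(self):
        """One spike still > 10% of peak a minute later (2 s rise, 30 s decay)."""
        kin = KINETICS["slow_hcrt"]
        t = np.array([0.0, 60_000.0, 200_000.0])
        g = synaptic_conductance_waveform(kin, [0.0], t + kin.delay_ms)
        peak = kin.gmax
        assert g[1] > 0.1 * peak
        assert g[2] < 0.01 * peak  # → 0 long after the spike

    def test_nonnegative_everywhere(self):
        kin = KINETICS["fast_gabaa"]
        t = np.arange(0.0, 500.0, 0.5)
        g = synaptic_conductance_waveform(kin, list(range(0, 400, 7)), t)
        assert (g >= 0.0).all()


class TestSingleNeuron:
    def test_resting_without_drive(self):
        p = NeuronParams(noise_amplitude=0.0, adapt_increment=0.0)
        tr = simulate_single_neuron(p, 0.0, duration=1000.0)
        assert len(tr.spike_times[0]) == 0
        assert abs(tr.voltages[-1, 0] + 65.0) < 2.0

    def test_adaptation_enforces_slow_tonic_firing(self):
        """The AHP conductance turns ~60 Hz bare firing into a few Hz."""
        bare = simulate_single_neuron(
            NeuronParams(noise_amplitude=0.0, adapt_increment=0.0), 15.0, 3000.0
        )
        adapted = simulate_single_neuron(
            NeuronParams(noise_amplitude=0.0, adapt_increment=0.5), 15.0, 3000.0
        )
        assert len(bare.spike_times[0]) > 100
        assert len(adapted.spike_times[0]) < 10

    def test_spike_count_converges_with_dt(self):
        """Halved step vs a 10× finer reference: counts differ by ≤ 1."""
        p = NeuronParams(noise_amplitude=0.0)
        counts = {}
        for dt in (0.05, 0.025, 0.005):
            tr = simulate_single_neuron(p, 20.0, duration=2000.0, dt=dt)
            counts[dt] = len(tr.spike_times[0])
        assert abs(counts[0.025] - counts[0.005]) <= 1
        assert abs(counts[0.05] - counts[0.005]) <= 1

    def test_voltages_bounded(self):
        tr = simulate_single_neuron(NeuronParams(), 20.0, duration=1000.0)
        assert tr.voltages.min() >= -100.0
        assert tr.voltages.max() <= 60.0

    def test_divergence_reported_with_neuron_and_time(self):
        p = NeuronParams(noise_amplitude=0.0)
        with pytest.raises(IntegrationError) as exc:
            simulate_single_neuron(p, 1e7, duration=100.0)
        assert exc.value.neuron == 0
        assert exc.value.time_ms >= 0.0


class TestNetwork:
    def test_identical_seeds_bit_identical(self):
        circ = build_circuit("fig1")
        pr = StimProtocol("Hcrt", "stimulate", 500.0, 2000.0,
                          pulse_freq_hz=20.0, pulse_width_ms=10.0, amplitude=15.0)
        a = biophys.integrate_network(circ, [pr], duration=4000.0, seed=7)
        b = biophys.integrate_network(circ, [pr], duration=4000.0, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.spike_times, b.spike_times))
        assert np.array_equal(a.voltages, b.voltages)

    def test_different_seeds_differ(self):
        circ = build_circuit("fig1")
        pr = StimProtocol("Hcrt", "stimulate", 500.0, 2000.0,
                          pulse_freq_hz=20.0, pulse_width_ms=10.0, amplitude=15.0)
        a = biophys.integrate_network(circ, [pr], duration=4000.0, seed=7)
        b = biophys.integrate_network(circ, [pr], duration=4000.0, seed=8)
        assert not np.array_equal(a.voltages, b.voltages)

    def test_noiseless_unstimulated_network_is_silent(self):
        circ = build_circuit("fig1", {"noise": 0.0})
        tr = biophys.integrate_network(circ, (), duration=10_000.0, seed=0)
        assert tr.mean_rate("Hcrt") <= 0.5
        assert tr.mean_rate("NE/LC") <= 0.5
        assert len(tr.timeline.intervals) == 1
        assert tr.timeline.intervals[0][2] == "sleep"

    def test_unknown_protocol_target_rejected(self):
        circ = build_circuit("fig1")
        pr = StimProtocol("His", "stimulate", 0.0, 1000.0, amplitude=5.0)
        with pytest.raises(ParameterError):
            biophys.integrate_network(circ, [pr], duration=2000.0, seed=0)

    def test_record_serialization_roundtrip(self, tmp_path):
        import h5py

        circ = build_circuit("fig1")
        tr = biophys.integrate_network(circ, (), duration=2000.0, seed=1)
        h5 = tmp_path / "trial.h5"
        tr.to_hdf5(str(h5))
        with h5py.File(str(h5)) as f:
            assert f["voltages"].shape == tr.voltages.shape
            assert f.attrs["seed"] == 1
        csv = tmp_path / "rates.csv"
        tr.rates_to_csv(str(csv))
        import pandas as pd

        df = pd.read_csv(csv)
        assert "NE/LC_hz" in df.columns
        sidecar = tr.sidecar_json()
        assert sidecar["seed"] == 1 and sidecar["timeline"] is not None

    def test_spike_times_strictly_increasing(self):
        circ = build_circuit("fig1")
        pr = StimProtocol("Hcrt", "stimulate", 100.0, 3000.0,
                          pulse_freq_hz=20.0, pulse_width_ms=10.0, amplitude=15.0)
        tr = biophys.integrate_network(circ, [pr], duration=4000.0, seed=2)
        for st in tr.spike_times:
            assert np.all(np.diff(st) > 0)

    def test_small_step_convergence_of_rates(self):
        """Halving dt changes the deterministic trial-mean rate < 5%."""
        circ = build_circuit("fig1", {"noise": 0.0, "populations.Hcrt.jitter": 0.0,
                                      "populations.NE/LC.jitter": 0.0})
        pr = StimProtocol("Hcrt", "stimulate", 1000.0, 8000.0,
                          pulse_freq_hz=20.0, pulse_width_ms=10.0, amplitude=15.0)
        r = {}
        for dt in (0.05, 0.025):
            tr = biophys.integrate_network(circ, [pr], duration=10_000.0,
                                           dt=dt, seed=4)
            r[dt] = tr.mean_rate("Hcrt", 1000.0, 9000.0)
        assert r[0.05] > 1.0
        assert abs(r[0.05] - r[0.025]) / r[0.025] < 0.05
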