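"""Single-compartment conductance-based neurons, synapses, and the network
integrator.

Every population uses the same spiking-neuron template — classic squid-type
transient Na / delayed-rectifier K / leak kinetics — extended with a
spike-triggered after-hyperpolarization (AHP) conductance that reproduces the
low tonic firing regimes of the arousal nuclei (locus-coeruleus NE cells fire
at 2–3 Hz during wake, not at the tens of Hz a bare Hodgkin–Huxley model
produces).  Populations differ only in their drive, noise, adaptation
strength, and afferent synapse types.

Synapses are difference-of-exponentials conductances.  The hypocretin
receptor conductance (``slow_hcrt``) has a 2 s rise and 30 s decay so that a
10-s presynaptic volley produces the delayed, minute-scale depolarization of
the NE/LC targets; glutamatergic and GABA_A components are millisecond-scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .errors import IntegrationError, ParameterError, ProtocolConflictError

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "PopulationSpec",
    "TrialRecord",
    "SimConfig",
    "KINETICS",
    "synaptic_conductance_waveform",
    "waveform_peak_time",
    "integrate_network",
    "run_trial",
    "simulate_single_neuron",
]

SYNAPSE_KINDS = (
    "fast_excitatory",
    "slow_hcrt",
    "fast_gabaa",
    "slow_inhibitory_peptide",
    "slow_histamine",
)
_FAST_KINDS = ("fast_excitatory", "fast_gabaa")
_INHIBITORY_KINDS = ("fast_gabaa", "slow_inhibitory_peptide")
_NOMINAL_REST_MV = -65.0


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of the shared spiking-neuron template.

    Units: capacitance µF/cm², conductances mS/cm², potentials mV, noise
    µA/cm² (white current noise, spectral amplitude per √ms), times ms.
    ``adapt_increment``/``adapt_tau`` parameterize the spike-triggered AHP
    conductance (reversal at E_K) that sets the slow tonic firing regime.
    ``drive`` is a constant background current.
    """

    capacitance: float = 1.0
    g_leak: float = 0.3
    g_na: float = 120.0
    g_k: float = 36.0
    e_leak: float = -54.4
    e_na: float = 50.0
    e_k: float = -77.0
    spike_threshold: float = -20.0
    noise_amplitude: float = 0.5
    adapt_increment: float = 0.5
    adapt_tau: float = 400.0
    drive: float = 0.0

    def __post_init__(self):
        if min(self.g_leak, self.g_na, self.g_k) < 0:
            raise ParameterError("conductances must be non-negative")
        if not (self.e_na > self.e_leak > self.e_k):
            raise ParameterError("require E_Na > E_leak > E_K")
        if self.noise_amplitude < 0:
            raise ParameterError("noise amplitude must be non-negative")
        if self.capacitance <= 0:
            raise ParameterError("capacitance must be positive")
        if self.adapt_increment < 0 or self.adapt_tau <= 0:
            raise ParameterError("invalid adaptation parameters")


@dataclass(frozen=True)
class SynapseKinetics:
    """Difference-of-exponentials synaptic conductance.

    ``gmax`` is the aggregate maximal conductance a postsynaptic neuron
    receives per presynaptic spike volley; individual connection weights are
    scaled by 1/(p·N_pre) so circuit behaviour is robust to population size.
    """

    kind: str
    rise_ms: float
    decay_ms: float
    e_rev: float
    gmax: float
    delay_ms: float = 1.0

    def __post_init__(self):
        if self.kind not in SYNAPSE_KINDS:
            raise ParameterError(f"unknown synapse kind {self.kind!r}")
        if not (self.decay_ms >= self.rise_ms > 0):
            raise ParameterError("require decay >= rise > 0")
        if self.kind == "slow_hcrt" and self.decay_ms < 10_000:
            raise ParameterError("slow_hcrt decay must be >= 10,000 ms")
        if self.kind in _FAST_KINDS and self.decay_ms > 20:
            raise ParameterError(f"{self.kind} decay must be <= 20 ms")
        if self.kind in _INHIBITORY_KINDS and self.e_rev >= _NOMINAL_REST_MV:
            raise ParameterError(
                f"{self.kind} reversal must be below the resting potential"
            )
        if self.gmax < 0 or self.delay_ms < 0:
            raise ParameterError("gmax and delay must be non-negative")


#: Default kinetics per synapse kind; ``gmax`` values are the shipped
#: circuit calibration and are overridden per edge by the circuit builders.
KINETICS = {
    "fast_excitatory": SynapseKinetics("fast_excitatory", 0.5, 5.0, 0.0, 0.05),
    "slow_hcrt": SynapseKinetics("slow_hcrt", 2000.0, 30_000.0, 0.0, 0.009),
    "fast_gabaa": SynapseKinetics("fast_gabaa", 0.5, 10.0, -80.0, 0.5),
    "slow_inhibitory_peptide": SynapseKinetics(
        "slow_inhibitory_peptide", 200.0, 20_000.0, -80.0, 0.0
    ),
    "slow_histamine": SynapseKinetics("slow_histamine", 50.0, 2000.0, 0.0, 0.002),
}


@dataclass(frozen=True)
class PopulationSpec:
    """A homogeneous (up to jitter) population of template neurons."""

    name: str
    size: int
    neuron: NeuronParams = field(default_factory=NeuronParams)
    p_intra: float = 0.0
    p_inter: float = 0.5
    jitter: float = 0.05

    def __post_init__(self):
        if self.size < 1:
            raise ParameterError("population size must be >= 1")
        for p in (self.p_intra, self.p_inter):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("connection probabilities must be in [0, 1]")
        if self.jitter < 0:
            raise ParameterError("jitter must be non-negative")


def waveform_peak_time(kin: SynapseKinetics) -> float:
    """Time to peak (ms, after delay) of the double-exponential waveform."""
    tr, td = kin.rise_ms, kin.decay_ms
    if td == tr:
        return tr
    return (tr * td / (td - tr)) * np.log(td / tr)


def _waveform_norm(kin: SynapseKinetics) -> float:
    tp = waveform_peak_time(kin)
    tr, td = kin.rise_ms, kin.decay_ms
    if td == tr:
        return 1.0  # alpha function (t/tau)·e^(1-t/tau) already peaks at 1
    return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))


def synaptic_conductance_waveform(
    kin: SynapseKinetics,
    spike_times_ms: Sequence[float],
    eval_times_ms: Sequence[float],
) -> np.ndarray:
    """Conductance time course (mS/cm²) for a train of presynaptic spikes.

    Each spike contributes a delayed double-exponential transient normalized
    to peak at ``kin.gmax``; contributions sum linearly.
    """
    t = np.asarray(eval_times_ms, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ParameterError("eval times must be a sorted 1-d sequence")
    g = np.zeros_like(t)
    tr, td = kin.rise_ms, kin.decay_ms
    norm = _waveform_norm(kin)
    for ts in spike_times_ms:
        dtau = t - (ts + kin.delay_ms)
        on = dtau > 0
        if not np.any(on):
            continue
        x = dtau[on]
        if td == tr:
            g[on] += kin.gmax * (x / tr) * np.exp(1.0 - x / tr)
        else:
            g[on] += kin.gmax * norm * (np.exp(-x / td) - np.exp(-x / tr))
    return g


# --------------------------------------------------------------------------
# trial containers


@dataclass
class SimConfig:
    """Trial-level integration and readout settings."""

    duration_ms: float = 60_000.0
    dt_ms: float = 0.05
    record_stride_ms: float = 1.0
    refractory_ms: float = 2.0
    rate_window_ms: float = 1000.0
    rate_step_ms: float = 50.0
    chunk_ms: float = 100.0
    wake_threshold_hz: float = 1.5
    wake_hysteresis_hz: float = 0.5
    wake_dwell_ms: float = 1000.0

    def __post_init__(self):
        if self.dt_ms > 0.1:
            raise ParameterError("dt must be <= 0.1 ms")
        if self.duration_ms < self.dt_ms:
            raise ParameterError("duration must be >= dt")


@dataclass
class TrialRecord:
    """Everything observed in one simulated trial."""

    time_ms: np.ndarray                 # recorded voltage grid
    voltages: np.ndarray                # (T, N) mV
    spike_times: list                   # per-neuron arrays (ms)
    populations: dict                   # name -> (start, stop) neuron index
    rates: "object"                     # DataFrame: time_ms + one column/population
    nc_rate: Optional[np.ndarray]       # neocortical unit on the rate grid
    timeline: "object"                  # readout.VigilanceTimeline
    seed: int
    dt_ms: float
    duration_ms: float
    protocols: list = field(default_factory=list)

    def population_spikes(self, name: str) -> list:
        lo, hi = self.populations[name]
        return self.spike_times[lo:hi]

    def mean_rate(self, name: str, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Trial-mean population rate (Hz) from spike counts in [t0, t1)."""
        if t1 is None:
            t1 = self.duration_ms
        lo, hi = self.populations[name]
        count = sum(
            int(np.sum((st >= t0) & (st < t1))) for st in self.spike_times[lo:hi]
        )
        return 1000.0 * count / ((t1 - t0) * (hi - lo))

    def rate_series(self, name: str):
        return (
            self.rates["time_ms"].to_numpy(),
            self.rates[name].to_numpy(),
        )

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("voltages", data=self.voltages)
            g = f.create_group("spikes")
            for i, st in enumerate(self.spike_times):
                g.create_dataset(str(i), data=np.asarray(st))
            f.attrs["seed"] = self.seed
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["duration_ms"] = self.duration_ms
            f.attrs["populations"] = json.dumps(
                {k: list(v) for k, v in self.populations.items()}
            )

    def sidecar_json(self) -> dict:
        return {
            "seed": self.seed,
            "dt_ms": self.dt_ms,
            "duration_ms": self.duration_ms,
            "populations": {k: list(v) for k, v in self.populations.items()},
            "protocols": [p.as_dict() if hasattr(p, "as_dict") else p for p in self.protocols],
            "timeline": self.timeline.as_dict() if self.timeline is not None else None,
        }

    def rates_to_csv(self, path: str) -> None:
        cols = {"time_ms": self.rates["time_ms"]}
        for name in self.populations:
            cols[f"{name}_hz"] = self.rates[name]
        import pandas as pd

        pd.DataFrame(cols).to_csv(path, index=False)


# --------------------------------------------------------------------------
# network assembly


class _CompiledNetwork:
    """Flat per-neuron/per-projection arrays consumed by the numba kernel."""

    def __init__(self, circuit, seed: int, dt: float):
        pops = list(circuit.populations)
        self.pop_names = [p.name for p in pops]
        sizes = [p.size for p in pops]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.slices = {
            p.name: (int(offsets[k]), int(offsets[k + 1])) for k, p in enumerate(pops)
        }
        N = int(offsets[-1])
        self.n_neurons = N
        K = len(pops)
        self.pop_size = np.array(sizes, dtype=np.int64)
        self.pop_of = np.empty(N, dtype=np.int64)
        for k in range(K):
            self.pop_of[offsets[k]:offsets[k + 1]] = k

        rng = np.random.default_rng([int(seed) % (2**31), 0xC1C])

        def arr(getter):
            out = np.empty(N)
            for k, p in enumerate(pops):
                out[offsets[k]:offsets[k + 1]] = getter(p.neuron)
            return out

        self.Cm = arr(lambda q: q.capacitance)
        self.gNa = arr(lambda q: q.g_na)
        self.gK = arr(lambda q: q.g_k)
        self.gL = arr(lambda q: q.g_leak)
        self.ENa = arr(lambda q: q.e_na)
        self.EK = arr(lambda q: q.e_k)
        self.EL = arr(lambda q: q.e_leak)
        self.Vth = arr(lambda q: q.spike_threshold)
        self.sigma = arr(lambda q: q.noise_amplitude)
        self.dg_ahp = arr(lambda q: q.adapt_increment)
        self.ahp_tau = arr(lambda q: q.adapt_tau)
        self.Idrive = arr(lambda q: q.drive)

        # multiplicative conductance jitter (per neuron, clipped at 3 s.d.)
        for k, p in enumerate(pops):
            if p.jitter > 0:
                lo, hi = int(offsets[k]), int(offsets[k + 1])
                fac = 1.0 + p.jitter * np.clip(
                    rng.standard_normal(hi - lo), -3.0, 3.0
                )
                self.gNa[lo:hi] *= fac
                self.gK[lo:hi] *= fac
                self.gL[lo:hi] *= fac

        # projections (spiking -> spiking edges carrying kinetics)
        pop_index = {p.name: k for k, p in enumerate(pops)}
        spec_of = {p.name: p for p in pops}
        edges = [
            e
            for e in circuit.edges
            if e.kinetics is not None
            and e.source in pop_index
            and e.target in pop_index
        ]
        P = len(edges)
        self.W = np.zeros((P, N, N))
        self.decA = np.empty(P)
        self.decB = np.empty(P)
        self.Erev = np.empty(P)
        self.delay_steps = np.empty(P, dtype=np.int64)
        self.norm = np.empty(P)
        max_delay = 1
        for p_i, e in enumerate(edges):
            kin = e.kinetics
            src = spec_of[e.source]
            p_conn = src.p_intra if e.source == e.target else src.p_inter
            slo, shi = self.slices[e.source]
            tlo, thi = self.slices[e.target]
            n_pre = shi - slo
            if p_conn <= 0:
                w = 0.0
                mask = np.zeros((thi - tlo, n_pre), dtype=bool)
            else:
                w = kin.gmax / (p_conn * n_pre)
                mask = rng.random((thi - tlo, n_pre)) < p_conn
            if e.source == e.target:
                np.fill_diagonal(mask, False)
            self.W[p_i, tlo:thi, slo:shi] = np.where(mask, w, 0.0)
            td = kin.decay_ms
            if td <= kin.rise_ms:
                td = kin.rise_ms * (1 + 1e-9)
            self.decA[p_i] = np.exp(-dt / td)
            self.decB[p_i] = np.exp(-dt / kin.rise_ms)
            self.Erev[p_i] = kin.e_rev
            self.norm[p_i] = _waveform_norm(kin)
            steps = max(1, int(round(kin.delay_ms / dt)))
            self.delay_steps[p_i] = steps
            max_delay = max(max_delay, steps)
        self.ring_len = max_delay + 1

        # neocortical rate unit and feedback paths
        nc = getattr(circuit, "nc", None)
        self.has_nc = 1 if nc is not None else 0
        self.nc_tau = nc.tau_ms if nc is not None else 1000.0
        self.nc_w = np.zeros(K)
        self.fb_out_gain = 0.0
        self.fb_state_gain = 0.0
        self.fb_target_pop = -1
        if nc is not None:
            for name, wgt in nc.weights.items():
                if name in pop_index:
                    self.nc_w[pop_index[name]] = wgt
            self.fb_out_gain = nc.output_feedback_gain
            self.fb_state_gain = nc.state_feedback_gain
            if nc.state_feedback_target in pop_index:
                self.fb_target_pop = pop_index[nc.state_feedback_target]

        # online arousal signal: NC when present, else NE/LC, else pop 0
        if self.has_nc:
            self.arous_pop = -1
        elif "NE/LC" in pop_index:
            self.arous_pop = pop_index["NE/LC"]
        else:
            self.arous_pop = 0
        self.pop_index = pop_index


def _initial_state(net: _CompiledNetwork, dt: float):
    minf, _, hinf, _, ninf, _ = _kernel.gate_tables(dt)
    v0 = _NOMINAL_REST_MV
    idx = int((v0 - _kernel.V_TAB_LO) / _kernel.V_TAB_STEP + 0.5)
    N = net.n_neurons
    return {
        "V": np.full(N, v0),
        "m": np.full(N, minf[idx]),
        "h": np.full(N, hinf[idx]),
        "n": np.full(N, ninf[idx]),
        "gahp": np.zeros(N),
        "A": np.zeros((net.W.shape[0], N)),
        "B": np.zeros((net.W.shape[0], N)),
        "ring": np.zeros((net.ring_len, N), dtype=np.uint8),
        "pop_rate_est": np.zeros(len(net.pop_size)),
        "nc_state": np.zeros(1),
        "last_spike": np.full(N, -(10**9), dtype=np.int64),
    }


def _protocol_arrays(protocols, net: _CompiledNetwork):
    from .optoprotocol import validate_protocol_set

    validate_protocol_set(protocols)
    S = len(protocols)
    pop = np.zeros(S, dtype=np.int64)
    mode = np.zeros(S, dtype=np.int64)
    on = np.zeros(S)
    off = np.zeros(S)
    period = np.zeros(S)
    width = np.zeros(S)
    amp = np.zeros(S)
    for q, pr in enumerate(protocols):
        if pr.target not in net.pop_index:
            raise ParameterError(
                f"protocol targets unknown population {pr.target!r}"
            )
        pop[q] = net.pop_index[pr.target]
        mode[q] = 1 if pr.mode == "stimulate" else -1
        on[q] = pr.onset_ms
        off[q] = pr.onset_ms + pr.duration_ms
        period[q] = 0.0 if pr.pulse_freq_hz is None else 1000.0 / pr.pulse_freq_hz
        width[q] = pr.pulse_width_ms or 0.0
        amp[q] = pr.amplitude
    return pop, mode, on, off, period, width, amp


_RATE_EST_TAU = 1000.0  # ms, online population-rate filter


def integrate_network(
    circuit,
    protocols: Sequence = (),
    duration: float = 60_000.0,
    dt: float = 0.05,
    seed: int = 0,
    config: Optional[SimConfig] = None,
    controller=None,
) -> TrialRecord:
    """Integrate a circuit under a protocol set and return the trial record.

    Deterministic given ``(circuit, protocols, duration, dt, seed)``.  Raises
    :class:`IntegrationError` if any membrane voltage leaves ±150 mV.  An
    optional closed-loop controller is consulted on its own control grid
    (a multiple of the 100-ms integration chunk) and may append protocols
    mid-trial.
    """
    if config is None:
        config = SimConfig(duration_ms=duration, dt_ms=dt)
    else:
        config = replace(config, duration_ms=duration, dt_ms=dt)
    net = _CompiledNetwork(circuit, seed, dt)
    state = _initial_state(net, dt)
    tabs = _kernel.gate_tables(dt)
    protocols = list(protocols)
    parrs = _protocol_arrays(protocols, net)

    n_steps_total = int(round(duration / dt))
    rec_stride = max(1, int(round(config.record_stride_ms / dt)))
    n_rows = (n_steps_total - 1) // rec_stride + 1
    v_rec = np.zeros((n_rows, net.n_neurons))
    chunk_steps = max(1, int(round(config.chunk_ms / dt)))
    refr_steps = max(1, int(round(config.refractory_ms / dt)))
    cap = net.n_neurons * (chunk_steps // refr_steps + 2)
    sp_t = np.zeros(cap)
    sp_i = np.zeros(cap, dtype=np.int64)
    rate_decay = float(np.exp(-dt / _RATE_EST_TAU))

    all_t: list = []
    all_i: list = []
    nc_trace = []
    step0 = 0
    chunk_idx = 0
    base_seed = int(seed) % (2**31)
    vigilance = "sleep"
    state_since = 0.0
    while step0 < n_steps_total:
        t_now = step0 * dt
        if controller is not None:
            arous = (
                state["nc_state"][0]
                if net.arous_pop < 0
                else state["pop_rate_est"][net.arous_pop]
            )
            vig_now = "wake" if arous > config.wake_threshold_hz else "sleep"
            if vig_now != vigilance:
                vigilance = vig_now
                state_since = t_now
            if t_now % controller.control_dt_ms < 0.5 * dt + 1e-9 or t_now == 0.0:
                from .optoprotocol import ControllerState

                cs = ControllerState(
                    time_ms=t_now,
                    rates_hz={
                        name: float(state["pop_rate_est"][net.pop_index[name]])
                        for name in net.pop_index
                    },
                    nc_rate_hz=float(state["nc_state"][0]),
                    vigilance=vigilance,
                    time_in_state_ms=t_now - state_since,
                )
                new = controller.step(cs)
                if new:
                    protocols.extend(new)
                    parrs = _protocol_arrays(protocols, net)
        n_steps = min(chunk_steps, n_steps_total - step0)
        chunk_seed = (base_seed * 1_000_003 + chunk_idx) % (2**31)
        nsp, err_i, err_step = _kernel.integrate_chunk(
            state["V"], state["m"], state["h"], state["n"], state["gahp"],
            state["A"], state["B"], state["ring"], state["pop_rate_est"],
            state["nc_state"], state["last_spike"],
            sp_t, sp_i, v_rec,
            step0, n_steps, dt, rec_stride,
            net.Cm, net.gNa, net.gK, net.gL, net.ENa, net.EK, net.EL,
            net.Vth, net.sigma, net.dg_ahp,
            np.exp(-dt / net.ahp_tau), net.Idrive,
            net.pop_of, net.pop_size,
            net.W, net.decA, net.decB, net.Erev, net.delay_steps, net.norm,
            *tabs,
            *parrs,
            net.has_nc, net.nc_tau, net.nc_w, net.fb_out_gain,
            net.fb_state_gain, net.fb_target_pop,
            net.arous_pop, config.wake_threshold_hz,
            rate_decay, _RATE_EST_TAU, refr_steps, chunk_seed,
        )
        if err_i >= 0:
            raise IntegrationError(int(err_i), float(err_step) * dt, 999.0)
        if nsp > 0:
            all_t.append(sp_t[:nsp].copy())
            all_i.append(sp_i[:nsp].copy())
        nc_trace.append(state["nc_state"][0])
        step0 += n_steps
        chunk_idx += 1

    if all_t:
        ts = np.concatenate(all_t)
        idx = np.concatenate(all_i)
    else:
        ts = np.zeros(0)
        idx = np.zeros(0, dtype=np.int64)
    spike_times = [np.sort(ts[idx == i]) for i in range(net.n_neurons)]

    from . import readout

    t_grid = np.arange(
        0.0, duration + 0.5 * config.rate_step_ms, config.rate_step_ms
    )
    import pandas as pd

    cols = {"time_ms": t_grid}
    for name, (lo, hi) in net.slices.items():
        cols[name] = readout.population_rate(
            spike_times[lo:hi],
            window_ms=config.rate_window_ms,
            step_ms=config.rate_step_ms,
            duration_ms=duration,
        )[1]
    rates = pd.DataFrame(cols)

    # neocortical rate resampled onto the rate grid (one sample per chunk)
    nc_rate = None
    if net.has_nc:
        chunk_t = np.arange(1, len(nc_trace) + 1) * config.chunk_ms
        nc_rate = np.interp(t_grid, chunk_t, np.asarray(nc_trace))
        rates["NC"] = nc_rate

    from .circuitry import ThresholdDevice

    device = ThresholdDevice(
        threshold_hz=config.wake_threshold_hz,
        hysteresis_hz=config.wake_hysteresis_hz,
        min_dwell_ms=config.wake_dwell_ms,
    )
    arousal = "NC" if net.has_nc else ("NE/LC" if "NE/LC" in net.slices else net.pop_names[0])
    timeline = readout.classify_vigilance(rates, device, signal=arousal)

    return TrialRecord(
        time_ms=np.arange(n_rows) * rec_stride * dt,
        voltages=v_rec,
        spike_times=spike_times,
        populations=dict(net.slices),
        rates=rates,
        nc_rate=nc_rate,
        timeline=timeline,
        seed=int(seed),
        dt_ms=dt,
        duration_ms=duration,
        protocols=protocols,
    )


def run_trial(circuit, protocols: Sequence, config: SimConfig, seed: int) -> TrialRecord:
    """One trial: integrate, classify vigilance, log the protocol timing."""
    return integrate_network(
        circuit,
        protocols,
        duration=config.duration_ms,
        dt=config.dt_ms,
        seed=seed,
        config=config,
    )


class _BareCircuit:
    """Minimal duck-typed circuit for single-population simulations."""

    def __init__(self, populations):
        self.populations = populations
        self.edges = []
        self.nc = None


def simulate_single_neuron(
    params: NeuronParams,
    current: float,
    duration: float = 2000.0,
    dt: float = 0.05,
    seed: int = 0,
) -> TrialRecord:
    """Convenience: one neuron under a constant injected current."""
    pop = PopulationSpec(
        "cell", 1, replace(params, drive=params.drive + current), jitter=0.0
    )
    return integrate_network(_BareCircuit([pop]), (), duration, dt, seed)
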