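"""Canonical simulation experiments on the shipped circuits.

Each function fixes the study conditions of one reference experiment —
protocol, trial length, observation windows — so that tests, the command
line and the reproduction script all run the identical configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from . import biophys
from .circuitry import build_circuit
from .optoprotocol import StimProtocol, default_stimulation, pulse_train_protocol
from .readout import (
    coherence_metric,
    elevated_duration,
    population_rate,
    rate_onset_time,
)

__all__ = [
    "Fig1Result",
    "fig1_experiment",
    "fig2_coherence_experiment",
    "fig4_stability_experiment",
    "sleep_baseline_rates",
    "wake_calibration_rate",
]

#: rate window (ms) used when a series feeds the spectral coherence
#: estimator: short enough to pass fluctuations in the 0.5–10 Hz band.
COHERENCE_RATE_WINDOW_MS = 200.0
COHERENCE_RATE_STEP_MS = 50.0


@dataclass
class Fig1Result:
    trial: biophys.TrialRecord
    hcrt_onset_ms: Optional[float]
    nelc_onset_ms: Optional[float]
    lag_ms: Optional[float]
    persistence_ms: float
    baseline_hz: float
    stim_offset_ms: float


def fig1_experiment(
    seed: int = 0,
    duration_ms: float = 120_000.0,
    stim_onset_ms: float = 10_000.0,
    stim_duration_ms: float = 10_000.0,
) -> Fig1Result:
    """The two-population reference trial: 10-s pulsed Hcrt stimulation.

    Measures the NE/LC activation lag relative to the Hcrt rate rise (both
    as first crossings of 0.5 Hz on a 200-ms rate window) and how long the
    NE/LC rate stays continuously above 0.2 Hz after stimulus offset.
    """
    circuit = build_circuit("fig1")
    protocol = pulse_train_protocol("Hcrt", stim_onset_ms, stim_duration_ms)
    trial = biophys.integrate_network(
        circuit, [protocol], duration=duration_ms, dt=0.05, seed=seed
    )
    fine: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for name in ("Hcrt", "NE/LC"):
        lo, hi = trial.populations[name]
        fine[name] = population_rate(
            trial.spike_times[lo:hi],
            COHERENCE_RATE_WINDOW_MS,
            COHERENCE_RATE_STEP_MS,
            duration_ms,
        )
    pre = stim_onset_ms - 1000.0
    h_on = rate_onset_time(*fine["Hcrt"], 0.5, after_ms=pre)
    n_on = rate_onset_time(*fine["NE/LC"], 0.5, after_ms=pre)
    offset = stim_onset_ms + stim_duration_ms
    # persistence on the smooth 1-s rate series: the fine series drops to
    # zero between spikes at the few-Hz tonic rates
    persistence = elevated_duration(*trial.rate_series("NE/LC"), offset, 0.2)
    baseline = trial.mean_rate("NE/LC", 0.0, stim_onset_ms)
    return Fig1Result(
        trial=trial,
        hcrt_onset_ms=h_on,
        nelc_onset_ms=n_on,
        lag_ms=None if h_on is None or n_on is None else n_on - h_on,
        persistence_ms=persistence,
        baseline_hz=baseline,
        stim_offset_ms=offset,
    )


def fig2_coherence_experiment(
    seed: int = 0,
    with_gaba: bool = True,
    duration_ms: float = 60_000.0,
    stim_amplitude: float = 15.0,
) -> Tuple[float, biophys.TrialRecord]:
    """Hcrt–NE/LC spectral coherence with or without the GABA pool.

    Hcrt receives 40 s of tonic depolarization so both principal
    populations express slow adaptation-paced rhythms; the GABA pool is
    silenced by zeroing its efferent conductances (topology unchanged, same
    seeds ⇒ identical noise streams).
    """
    overrides = {}
    if not with_gaba:
        overrides = {
            "edges.GABA->Hcrt.fast_gabaa.gmax": 0.0,
            "edges.GABA->NE/LC.fast_gabaa.gmax": 0.0,
        }
    circuit = build_circuit("fig2", overrides)
    protocol = StimProtocol(
        "Hcrt", "stimulate", 5_000.0, duration_ms - 20_000.0,
        amplitude=stim_amplitude,
    )
    trial = biophys.integrate_network(
        circuit, [protocol], duration=duration_ms, dt=0.05, seed=seed
    )
    series = {}
    for name in ("Hcrt", "NE/LC"):
        lo, hi = trial.populations[name]
        series[name] = population_rate(
            trial.spike_times[lo:hi],
            COHERENCE_RATE_WINDOW_MS,
            COHERENCE_RATE_STEP_MS,
            duration_ms,
        )[1]
    fs = 1000.0 / COHERENCE_RATE_STEP_MS
    return coherence_metric(series["Hcrt"], series["NE/LC"], fs_hz=fs), trial


def fig4_stability_experiment(
    seed: int = 0,
    duration_ms: float = 40_000.0,
    ceiling_hz: float = 30.0,
) -> Tuple[Dict[str, float], biophys.TrialRecord]:
    """Full-circuit stability check under default Hcrt stimulation.

    Returns each population's peak rate (1-s window); the histaminergic and
    GABA-balanced circuit must keep every population below the
    over-excitation ceiling during and after stimulation.
    """
    circuit = build_circuit("fig4")
    protocol = default_stimulation("Hcrt", 5_000.0, 10_000.0)
    trial = biophys.integrate_network(
        circuit, [protocol], duration=duration_ms, dt=0.05, seed=seed
    )
    peaks = {
        name: float(np.max(trial.rates[name])) for name in trial.populations
    }
    return peaks, trial


def sleep_baseline_rates(
    seed: int = 0, duration_ms: float = 20_000.0, level: str = "fig1"
) -> Dict[str, float]:
    """Unstimulated mean rates (Hz): the quiescent NREM regime."""
    circuit = build_circuit(level)
    trial = biophys.integrate_network(
        circuit, (), duration=duration_ms, dt=0.05, seed=seed
    )
    return {name: trial.mean_rate(name) for name in trial.populations}


def wake_calibration_rate(
    seed: int = 0, duration_ms: float = 30_000.0
) -> float:
    """Mean NE/LC rate under direct tonic stimulation to the wake regime."""
    circuit = build_circuit("fig1")
    protocol = default_stimulation("NE/LC", 2_000.0, duration_ms - 2_000.0)
    trial = biophys.integrate_network(
        circuit, [protocol], duration=duration_ms, dt=0.05, seed=seed
    )
    return trial.mean_rate("NE/LC", 4_000.0, duration_ms)
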