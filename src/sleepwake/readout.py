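"""Observables: spike detection, population rates, spectral coherence, the
binary vigilance timeline, and the sleep-to-wake transition probability
P[S-to-W].

Vigilance is deliberately binary (sleep vs wake): the modeled transition is
the NREM-to-wake transition, and EEG staging is out of scope.  The
transition probability under a protocol is estimated as the fraction of
independent trials with at least one sleep→wake crossing inside an
observation window (default: protocol onset to onset + 30 s), with a Wilson
95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _sig

from .circuitry import ThresholdDevice, threshold_device
from .errors import ParameterError

__all__ = [
    "VigilanceTimeline",
    "TransitionEstimate",
    "wilson_interval",
    "detect_spikes",
    "population_rate",
    "coherence_metric",
    "classify_vigilance",
    "estimate_transition_probability",
    "rate_onset_time",
    "elevated_duration",
]


@dataclass(frozen=True)
class TransitionEstimate:
    """Estimated P[S-to-W] with a Wilson 95% interval."""

    p_hat: float
    n_trials: int
    ci_low: float
    ci_high: float
    window_ms: Tuple[float, float] = (0.0, 30_000.0)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ParameterError("require 0 <= ci_low <= p_hat <= ci_high <= 1")

    def as_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "n_trials": self.n_trials,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "window_ms": list(self.window_ms),
        }

    @classmethod
    def from_counts(
        cls, k: int, n: int, window_ms: Tuple[float, float] = (0.0, 30_000.0)
    ) -> "TransitionEstimate":
        lo, hi = wilson_interval(k, n)
        # the score interval can exclude the raw proportion at k=0 / k=n;
        # widen minimally so the estimate always lies inside its interval
        p = k / n
        return cls(p, n, min(lo, p), max(hi, p), tuple(window_ms))

    @classmethod
    def exact(cls, p: float, window_ms=(0.0, 30_000.0)) -> "TransitionEstimate":
        """Degenerate estimate for a closed-form probability (CI collapsed)."""
        return cls(p, 1, p, p, tuple(window_ms))


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion (default 95%)."""
    if n < 1 or not 0 <= k <= n:
        raise ParameterError("need 0 <= k <= n, n >= 1")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(0.0, center - half), min(1.0, center + half)


@dataclass
class VigilanceTimeline:
    """Contiguous sleep/wake intervals covering one trial."""

    intervals: List[Tuple[float, float, str]]  # (start_ms, end_ms, state)
    transitions: List[float] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = [(float(a), float(b), s) for a, b, s in self.intervals]
        for (a0, a1, s), (b0, b1, _) in zip(self.intervals, self.intervals[1:]):
            if not np.isclose(a1, b0):
                raise ParameterError("timeline intervals must be contiguous")
        self.transitions = [
            b0
            for (a0, a1, sa), (b0, b1, sb) in zip(self.intervals, self.intervals[1:])
            if sa == "sleep" and sb == "wake"
        ]

    def state_at(self, t_ms: float) -> str:
        for a, b, s in self.intervals:
            if a <= t_ms < b:
                return s
        return self.intervals[-1][2]

    def has_transition_in(self, t0: float, t1: float) -> bool:
        return any(t0 <= t < t1 for t in self.transitions)

    def total(self, state: str) -> float:
        return sum(b - a for a, b, s in self.intervals if s == state)

    def as_dict(self) -> dict:
        return {
            "intervals": [list(iv) for iv in self.intervals],
            "transitions": list(self.transitions),
        }


# --------------------------------------------------------------------------
# spikes and rates


def detect_spikes(
    voltage: np.ndarray,
    times_ms: np.ndarray,
    threshold_mv: float = -20.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Upward threshold crossings with refractory suppression."""
    v = np.asarray(voltage, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    cross = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv)) + 1
    out = []
    last = -np.inf
    for i in cross:
        if t[i] - last >= refractory_ms:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


def population_rate(
    spike_trains: Sequence[np.ndarray],
    window_ms: float = 1000.0,
    step_ms: float = 50.0,
    duration_ms: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window population rate in Hz.

    Rate at grid time t is the spike count in the centered window divided by
    (effective window length × population size); the window is clipped at
    the trial boundaries.
    """
    if not spike_trains:
        raise ParameterError("empty population")
    if not (window_ms >= step_ms > 0):
        raise ParameterError("require window >= step > 0")
    if duration_ms is None:
        duration_ms = max((float(st[-1]) if len(st) else 0.0) for st in spike_trains)
    t_grid = np.arange(0.0, duration_ms + 0.5 * step_ms, step_ms)
    all_spikes = (
        np.sort(np.concatenate([np.asarray(s) for s in spike_trains]))
        if any(len(s) for s in spike_trains)
        else np.zeros(0)
    )
    n = len(spike_trains)
    half = window_ms / 2.0
    lo = np.clip(t_grid - half, 0.0, duration_ms)
    hi = np.clip(t_grid + half, 0.0, duration_ms)
    counts = np.searchsorted(all_spikes, hi, side="right") - np.searchsorted(
        all_spikes, lo, side="left"
    )
    eff = np.maximum(hi - lo, step_ms)
    return t_grid, 1000.0 * counts / (eff * n)


def coherence_metric(
    series_a: np.ndarray,
    series_b: np.ndarray,
    fs_hz: float,
    band_hz: Tuple[float, float] = (0.5, 10.0),
    segment_s: float = 4.0,
) -> float:
    """Peak magnitude-squared coherence between two rate series in a band.

    Welch-style segment averaging (default 4-s segments, 50% overlap).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("series must have equal length")
    nperseg = int(round(segment_s * fs_hz))
    if a.size < 2.5 * nperseg:
        raise ParameterError("series shorter than 4 spectral segments")
    if band_hz[1] > fs_hz / 2.0:
        raise ParameterError("band exceeds Nyquist")
    f, cxy = _sig.coherence(a, b, fs=fs_hz, nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    if not np.any(sel):
        raise ParameterError("no spectral estimate inside the band")
    return float(np.clip(np.max(cxy[sel]), 0.0, 1.0))


# --------------------------------------------------------------------------
# vigilance classification


def classify_vigilance(
    rates, device: ThresholdDevice, signal: str = "NE/LC"
) -> VigilanceTimeline:
    """Threshold-device classification of the arousal signal into a timeline.

    ``rates`` is the trial's rate DataFrame (``time_ms`` plus one column per
    population); wake is declared where the device output on the chosen
    arousal column is 1.
    """
    t = np.asarray(rates["time_ms"], dtype=float)
    x = np.asarray(rates[signal], dtype=float)
    step = float(t[1] - t[0]) if t.size > 1 else 1.0
    out = threshold_device(x, device, step_ms=step)
    intervals: List[Tuple[float, float, str]] = []
    start = t[0]
    cur = "wake" if out[0] else "sleep"
    for i in range(1, out.size):
        s = "wake" if out[i] else "sleep"
        if s != cur:
            intervals.append((start, t[i], cur))
            start = t[i]
            cur = s
    end = t[-1] + step
    intervals.append((start, end, cur))
    return VigilanceTimeline(intervals)


def rate_onset_time(
    t_ms: np.ndarray, rate_hz: np.ndarray, threshold_hz: float, after_ms: float = 0.0
) -> Optional[float]:
    """First time after ``after_ms`` the rate exceeds a threshold."""
    sel = np.flatnonzero((t_ms >= after_ms) & (rate_hz > threshold_hz))
    return float(t_ms[sel[0]]) if sel.size else None


def elevated_duration(
    t_ms: np.ndarray,
    rate_hz: np.ndarray,
    from_ms: float,
    floor_hz: float,
) -> float:
    """Continuous duration (ms) the rate stays above ``floor_hz`` from a time."""
    sel = t_ms >= from_ms
    t = t_ms[sel]
    r = rate_hz[sel]
    below = np.flatnonzero(r < floor_hz)
    if below.size == 0:
        return float(t[-1] - from_ms)
    return float(t[below[0]] - from_ms)


# --------------------------------------------------------------------------
# transition probability


def estimate_transition_probability(
    circuit,
    protocols: Sequence,
    n_trials: int,
    seed: int = 0,
    window_ms: Optional[Tuple[float, float]] = None,
    config=None,
    trial_runner: Optional[Callable] = None,
) -> TransitionEstimate:
    """Monte-Carlo estimate of P[S-to-W] under a protocol set.

    Trials use seeds ``seed, seed+1, …``; a success is a trial whose
    vigilance timeline contains a sleep→wake transition inside the
    observation window (default: first protocol onset to onset + 30 s).
    """
    from . import biophys

    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if config is None:
        config = biophys.SimConfig()
    if window_ms is None:
        onset = min((p.onset_ms for p in protocols), default=0.0)
        window_ms = (onset, onset + 30_000.0)
    if window_ms[1] > config.duration_ms or window_ms[0] < 0:
        raise ParameterError("observation window outside the simulated duration")
    runner = trial_runner or (
        lambda s: biophys.run_trial(circuit, protocols, config, seed=s)
    )
    k = 0
    for i in range(n_trials):
        trial = runner(seed + i)
        if trial.timeline.has_transition_in(*window_ms):
            k += 1
    return TransitionEstimate.from_counts(k, n_trials, window_ms)
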