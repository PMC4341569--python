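"""Optogenetic stimulation/inhibition protocols, the combinatorial
stimulation-pattern generator, and the closed-loop controller.

Stimulation is modeled as square current pulses injected into every neuron
of the targeted population (pulsed for phasically-driven populations,
constant for tonically-driven ones); inhibition is a constant
hyperpolarizing current.  Opsin photocycle kinetics are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence

from .errors import ParameterError, ProtocolConflictError

__all__ = [
    "StimProtocol",
    "PatternAssignment",
    "pulse_train_protocol",
    "inhibition_protocol",
    "default_stimulation",
    "default_inhibition",
    "combinatorial_patterns",
    "protocols_for_pattern",
    "validate_protocol_set",
    "ControlRule",
    "ClosedLoopController",
]

MODES = ("stimulate", "inhibit", "off")

#: Populations driven phasically (pulse trains) rather than tonically.
_PULSED_POPULATIONS = {"Hcrt"}

DEFAULT_PULSE_FREQ_HZ = 20.0
DEFAULT_PULSE_WIDTH_MS = 10.0
DEFAULT_PULSE_AMP = 15.0        # µA/cm²
DEFAULT_TONIC_AMP = 21.0        # µA/cm², sets the 2–3 Hz tonic wake regime
DEFAULT_INHIB_AMP = 5.0         # µA/cm² hyperpolarizing
DEFAULT_STIM_DURATION_MS = 10_000.0


@dataclass(frozen=True)
class StimProtocol:
    """One optogenetic actuation epoch on one population."""

    target: str
    mode: str
    onset_ms: float = 0.0
    duration_ms: float = 0.0
    pulse_freq_hz: Optional[float] = None   # None → constant current
    pulse_width_ms: Optional[float] = None
    amplitude: float = DEFAULT_PULSE_AMP    # µA/cm², magnitude

    def __post_init__(self):
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode != "off":
            if self.duration_ms <= 0:
                raise ParameterError("duration must be positive")
            if self.amplitude <= 0:
                raise ParameterError("amplitude must be positive")
        if self.pulse_freq_hz is not None:
            if self.pulse_freq_hz <= 0:
                raise ParameterError("pulse frequency must be positive")
            if self.pulse_width_ms is None or self.pulse_width_ms <= 0:
                raise ParameterError("pulsed protocols need a positive width")
            if self.pulse_width_ms >= 1000.0 / self.pulse_freq_hz:
                raise ParameterError("pulse width must be below the period")

    @property
    def n_pulses(self) -> int:
        if self.pulse_freq_hz is None:
            return 0
        return int(self.duration_ms / 1000.0 * self.pulse_freq_hz)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "mode": self.mode,
            "onset_ms": self.onset_ms,
            "duration_ms": self.duration_ms,
            "pulse_freq_hz": self.pulse_freq_hz,
            "pulse_width_ms": self.pulse_width_ms,
            "amplitude": self.amplitude,
        }


def pulse_train_protocol(
    target: str,
    onset_ms: float,
    duration_ms: float,
    freq_hz: float = DEFAULT_PULSE_FREQ_HZ,
    width_ms: float = DEFAULT_PULSE_WIDTH_MS,
    amplitude: float = DEFAULT_PULSE_AMP,
) -> StimProtocol:
    """Square pulse-train stimulation of one population."""
    return StimProtocol(
        target=target,
        mode="stimulate",
        onset_ms=onset_ms,
        duration_ms=duration_ms,
        pulse_freq_hz=freq_hz,
        pulse_width_ms=width_ms,
        amplitude=amplitude,
    )


def inhibition_protocol(
    target: str,
    onset_ms: float,
    duration_ms: float,
    amplitude: float = DEFAULT_INHIB_AMP,
) -> StimProtocol:
    """Sustained hyperpolarizing current (continuous, not pulsed)."""
    return StimProtocol(
        target=target,
        mode="inhibit",
        onset_ms=onset_ms,
        duration_ms=duration_ms,
        amplitude=amplitude,
    )


def default_stimulation(
    target: str,
    onset_ms: float = 0.0,
    duration_ms: float = DEFAULT_STIM_DURATION_MS,
) -> StimProtocol:
    """The shipped per-population stimulation default.

    Hcrt neurons fire phasically and are driven with a 20-Hz/10-ms pulse
    train; tonically active nuclei (NE/LC, His, ...) receive a constant
    suprathreshold current whose adapted firing lands in the tonic band.
    """
    if target in _PULSED_POPULATIONS:
        return pulse_train_protocol(target, onset_ms, duration_ms)
    return StimProtocol(
        target=target,
        mode="stimulate",
        onset_ms=onset_ms,
        duration_ms=duration_ms,
        amplitude=DEFAULT_TONIC_AMP,
    )


def default_inhibition(
    target: str,
    onset_ms: float = 0.0,
    duration_ms: float = DEFAULT_STIM_DURATION_MS,
) -> StimProtocol:
    return inhibition_protocol(target, onset_ms, duration_ms)


def validate_protocol_set(protocols: Sequence[StimProtocol]) -> None:
    """Reject same-population protocols that overlap in time.

    Concurrent protocols on different populations compose by current
    summation; overlapping epochs on one population are ambiguous and are
    treated as configuration errors.
    """
    by_target: Dict[str, list] = {}
    for p in protocols:
        if p.mode == "off":
            continue
        by_target.setdefault(p.target, []).append(p)
    for target, plist in by_target.items():
        plist = sorted(plist, key=lambda p: p.onset_ms)
        for a, b in zip(plist, plist[1:]):
            if b.onset_ms < a.onset_ms + a.duration_ms:
                raise ProtocolConflictError(
                    f"overlapping protocols on population {target!r}"
                )


# --------------------------------------------------------------------------
# combinatorial patterns

PatternAssignment = Dict[str, str]  # population -> "stimulate" | "inhibit"


def combinatorial_patterns(targets: Sequence[str]) -> List[PatternAssignment]:
    """All 2^n stimulate/inhibit assignments over the target populations.

    Ordered lexicographically with ``inhibit`` (0) before ``stimulate`` (1),
    i.e. binary counting from all-inhibit to all-stimulate.
    """
    targets = list(targets)
    if not targets:
        raise ParameterError("targets must be non-empty")
    if len(set(targets)) != len(targets):
        raise ParameterError("duplicate targets")
    out = []
    for bits in itertools.product((0, 1), repeat=len(targets)):
        out.append(
            {t: ("stimulate" if b else "inhibit") for t, b in zip(targets, bits)}
        )
    return out


def protocols_for_pattern(
    pattern: PatternAssignment,
    onset_ms: float = 0.0,
    duration_ms: float = DEFAULT_STIM_DURATION_MS,
) -> List[StimProtocol]:
    """Concrete protocol set realizing one stimulation/inhibition pattern."""
    protos = []
    for target, mode in pattern.items():
        if mode == "stimulate":
            protos.append(default_stimulation(target, onset_ms, duration_ms))
        elif mode == "inhibit":
            protos.append(default_inhibition(target, onset_ms, duration_ms))
        else:
            raise ParameterError(f"pattern mode must be stimulate/inhibit, got {mode!r}")
    return protos


# --------------------------------------------------------------------------
# closed-loop controller


@dataclass
class ControlRule:
    """condition → protocol template.

    ``condition(state) -> bool`` receives a :class:`ControllerState`;
    ``protocol`` is a template whose onset is re-anchored to the control
    step at which the rule fires.
    """

    condition: Callable[["ControllerState"], bool]
    protocol: StimProtocol
    name: str = ""


@dataclass
class ControllerState:
    """What the controller can observe at a control step."""

    time_ms: float
    rates_hz: Dict[str, float]      # online population-rate estimates
    nc_rate_hz: float
    vigilance: str                  # "sleep" | "wake"
    time_in_state_ms: float


class ClosedLoopController:
    """Rule-based optogenetic controller evaluated on a coarse grid.

    At each control step (default 100 ms) rules are evaluated in order and
    the first whose condition holds activates its protocol; while a
    protocol is active no new rule fires.  By default actuation is limited
    to the three controller nodes of the feedback schematic (Hcrt, NE/LC
    and the neocortex — NC actuation is interpreted as actuation of its
    NE/LC afferents and is disallowed here unless explicitly permitted).
    """

    DEFAULT_ALLOWED = ("Hcrt", "NE/LC", "NC")

    def __init__(
        self,
        rules: Sequence[ControlRule],
        control_dt_ms: float = 100.0,
        allowed_targets: Optional[Sequence[str]] = None,
        known_populations: Optional[Sequence[str]] = None,
    ):
        self.rules = list(rules)
        self.control_dt_ms = control_dt_ms
        self.allowed = tuple(
            allowed_targets if allowed_targets is not None else self.DEFAULT_ALLOWED
        )
        for r in self.rules:
            if r.protocol.target not in self.allowed:
                raise ParameterError(
                    f"rule actuates {r.protocol.target!r}, not an allowed node"
                )
            if known_populations is not None and r.protocol.target not in known_populations:
                raise ParameterError(
                    f"rule references unknown population {r.protocol.target!r}"
                )
        self._active_until = -1.0
        self.log: List[dict] = []

    def step(self, state: ControllerState) -> List[StimProtocol]:
        """Evaluate rules; return protocols to activate at this step."""
        if state.time_ms < self._active_until:
            return []
        for r in self.rules:
            if r.condition(state):
                proto = replace(r.protocol, onset_ms=state.time_ms)
                self._active_until = state.time_ms + proto.duration_ms
                self.log.append(
                    {"time_ms": state.time_ms, "rule": r.name, "target": proto.target}
                )
                return [proto]
        return []


def sleep_longer_than(threshold_ms: float) -> Callable[[ControllerState], bool]:
    """Condition: continuously asleep for more than ``threshold_ms``."""

    def cond(state: ControllerState) -> bool:
        return state.vigilance == "sleep" and state.time_in_state_ms > threshold_ms

    return cond
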