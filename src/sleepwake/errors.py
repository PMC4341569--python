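"""Exception types shared across the package."""


class SleepWakeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SleepWakeError, ValueError):
    """A parameter or configuration value violates its invariants."""


class IntegrationError(SleepWakeError, RuntimeError):
    """Numerical divergence during network integration.

    Carries the index of the offending neuron and the simulation time (ms)
    at which the voltage left the admissible range.
    """

    def __init__(self, neuron: int, time_ms: float, voltage: float):
        self.neuron = neuron
        self.time_ms = time_ms
        self.voltage = voltage
        super().__init__(
            f"voltage diverged: neuron {neuron} reached {voltage:.1f} mV "
            f"at t = {time_ms:.2f} ms (|V| > 150 mV)"
        )


class ProtocolConflictError(SleepWakeError, ValueError):
    """Two protocols overlap in time on the same target population."""


class ComparabilityError(SleepWakeError, ValueError):
    """Probabilistic dominance queried for an incomparable codeword pair."""


class ConfigValidationError(SleepWakeError, ValueError):
    """An experiment configuration violates one or more invariants.

    ``violations`` lists every violated invariant, not only the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
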