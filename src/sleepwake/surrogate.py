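"""Analytically tractable logistic surrogate of the transition probability.

The surrogate maps a perturbation vector x (one entry per unit: +1
stimulated, 0 untouched, −1 inhibited — codebook patterns use {0, 1}) to
P[wake] = logistic(w·x + b).  It exists so the gating and codebook
machinery can be verified against closed-form probabilities; no claim is
made that the biology is logistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .readout import TransitionEstimate

__all__ = ["SurrogateModel", "surrogate_estimator", "brute_force_table"]


@dataclass(frozen=True)
class SurrogateModel:
    weights: tuple
    bias: float = 0.0
    labels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.labels and len(self.labels) != len(self.weights):
            raise ParameterError("labels must match weights")

    def probability(self, pattern: Sequence[float]) -> float:
        """Closed-form P[wake | pattern]."""
        x = np.asarray(pattern, dtype=float)
        if x.shape != (len(self.weights),):
            raise ParameterError(
                f"pattern length {x.size} != weight count {len(self.weights)}"
            )
        z = float(np.dot(self.weights, x) + self.bias)
        return 1.0 / (1.0 + np.exp(-z))


def surrogate_estimator(
    model: SurrogateModel,
    pattern: Sequence[float],
    n_trials: int,
    seed: int = 0,
) -> TransitionEstimate:
    """Monte-Carlo Bernoulli estimate at the surrogate's closed-form p."""
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    p = model.probability(pattern)
    rng = np.random.default_rng(int(seed) % (2**31))
    k = int(rng.binomial(n_trials, p))
    return TransitionEstimate.from_counts(k, n_trials)


def brute_force_table(model: SurrogateModel, codebook) -> "object":
    """Exact conditional-probability table over a codebook (oracle).

    Every non-LSB pattern is mapped to its closed-form probability with the
    confidence interval collapsed to the point.
    """
    from .codebook import CodewordProbabilityTable, unit_patterns

    entries = {}
    for pattern in unit_patterns(codebook.layout):
        p = model.probability(pattern)
        entries[pattern] = TransitionEstimate.exact(p)
    return CodewordProbabilityTable(layout=codebook.layout, entries=entries)
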