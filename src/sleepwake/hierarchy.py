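"""The pairwise hierarchical-gating test.

Circuit B *hierarchically gates* circuit A in inducing a sleep-to-wake
transition when, writing a, b, c for P[S-to-W] under (A stimulated alone),
(A stimulated + B inhibited) and (A and B both stimulated):

    a > b  and  c > a.

The inequalities are defined on true probabilities; with finite trials a
decision rule is needed.  Two are provided: ``point`` (strict inequality of
the estimates) and the default ``ci`` (the Wilson intervals of the compared
conditions must be disjoint).  Ties are conservatively not gating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .errors import ParameterError
from .readout import TransitionEstimate, estimate_transition_probability

__all__ = [
    "GatingResult",
    "ConditionEstimator",
    "SimulatorEngine",
    "SurrogateEngine",
    "gating_test",
    "gating_scan",
]

#: estimator of P[S-to-W] for one condition:
#: (stimulated populations, inhibited populations, n_trials, seed) -> estimate
ConditionEstimator = Callable[
    [Sequence[str], Sequence[str], int, int], TransitionEstimate
]


@dataclass
class GatingResult:
    a_pop: str
    b_pop: str
    a: float
    b: float
    c: float
    verdict: bool
    decision_rule: str
    estimates: Dict[str, TransitionEstimate] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "a_pop": self.a_pop,
            "b_pop": self.b_pop,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "verdict": self.verdict,
            "decision_rule": self.decision_rule,
            "estimates": {k: v.as_dict() for k, v in self.estimates.items()},
            "flags": list(self.flags),
        }


class SimulatorEngine:
    """Condition estimator backed by the conductance-based simulator.

    Stimulated populations receive their per-population default protocol
    (pulsed for Hcrt, tonic otherwise); inhibited populations receive the
    sustained hyperpolarizing default.  Protocols share onset and duration
    so the three gating conditions are matched.
    """

    def __init__(
        self,
        circuit,
        onset_ms: float = 2000.0,
        duration_ms: float = 10_000.0,
        trial_ms: float = 32_000.0,
        window_ms: float = 30_000.0,
        config=None,
    ):
        from .biophys import SimConfig

        self.circuit = circuit
        self.onset_ms = onset_ms
        self.duration_ms = duration_ms
        self.window = (onset_ms, onset_ms + window_ms)
        self.config = config or SimConfig(duration_ms=trial_ms)

    def __call__(self, stim, inhib, n_trials, seed) -> TransitionEstimate:
        from .optoprotocol import default_inhibition, default_stimulation

        protocols = [
            default_stimulation(p, self.onset_ms, self.duration_ms) for p in stim
        ] + [
            # inhibition covers the whole observation window
            default_inhibition(p, 0.0, self.config.duration_ms) for p in inhib
        ]
        return estimate_transition_probability(
            self.circuit,
            protocols,
            n_trials=n_trials,
            seed=seed,
            window_ms=self.window,
            config=self.config,
        )


class SurrogateEngine:
    """Condition estimator backed by the logistic surrogate.

    Populations map to surrogate inputs +1 (stimulated), −1 (inhibited) and
    0 (untouched).  ``exact=True`` returns closed-form probabilities with
    collapsed intervals (the brute-force oracle)."""

    def __init__(self, model, pop_to_index: Dict[str, int], exact: bool = False):
        self.model = model
        self.pop_to_index = dict(pop_to_index)
        self.exact = exact

    def __call__(self, stim, inhib, n_trials, seed) -> TransitionEstimate:
        from .surrogate import surrogate_estimator

        x = [0.0] * len(self.model.weights)
        for p in stim:
            x[self.pop_to_index[p]] = 1.0
        for p in inhib:
            x[self.pop_to_index[p]] = -1.0
        if self.exact:
            return TransitionEstimate.exact(self.model.probability(x))
        return surrogate_estimator(self.model, x, n_trials, seed)


def _greater(e1: TransitionEstimate, e2: TransitionEstimate, rule: str) -> bool:
    if rule == "point":
        return e1.p_hat > e2.p_hat
    if rule == "ci":
        return e1.ci_low > e2.ci_high
    raise ParameterError(f"unknown decision rule {rule!r}")


def gating_test(
    a_pop: str,
    b_pop: str,
    estimator: ConditionEstimator,
    n_trials: int = 20,
    seed: int = 0,
    decision_rule: str = "ci",
) -> GatingResult:
    """Run the three matched gating conditions and apply the decision rule.

    Condition seeds are ``seed``, ``seed + n_trials`` and
    ``seed + 2·n_trials`` so conditions never share trial seeds.
    """
    if a_pop == b_pop:
        raise ParameterError("gating test requires two distinct populations")
    est_a = estimator([a_pop], [], n_trials, seed)
    est_b = estimator([a_pop], [b_pop], n_trials, seed + n_trials)
    est_c = estimator([a_pop, b_pop], [], n_trials, seed + 2 * n_trials)
    flags = []
    if est_a.p_hat == est_c.p_hat:
        flags.append("c equals a: gating undefined at the boundary, treated as false")
    if est_a.p_hat == est_b.p_hat:
        flags.append("a equals b: tie treated as false")
    verdict = _greater(est_a, est_b, decision_rule) and _greater(
        est_c, est_a, decision_rule
    )
    return GatingResult(
        a_pop=a_pop,
        b_pop=b_pop,
        a=est_a.p_hat,
        b=est_b.p_hat,
        c=est_c.p_hat,
        verdict=verdict,
        decision_rule=decision_rule,
        estimates={"a": est_a, "b": est_b, "c": est_c},
        flags=flags,
    )


def gating_scan(
    populations: Sequence[str],
    estimator: ConditionEstimator,
    n_trials: int = 20,
    seed: int = 0,
    decision_rule: str = "ci",
) -> List[GatingResult]:
    """Pairwise gating scan: the test over all ordered population pairs."""
    results = []
    for i, (a, b) in enumerate(itertools.permutations(populations, 2)):
        results.append(
            gating_test(
                a, b, estimator,
                n_trials=n_trials,
                seed=seed + 3 * n_trials * i,
                decision_rule=decision_rule,
            )
        )
    return results
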