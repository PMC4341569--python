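"""Experiment configuration, validation, dispatch, and persistence.

An :class:`ExperimentConfig` describes one run — circuit or surrogate
engine, protocol set, trial counts, seeds, output directory — and
round-trips losslessly through YAML.  ``run_experiment`` validates the
configuration (reporting *every* violated invariant), dispatches to the
appropriate analysis, and writes JSON plus tidy CSV results stamped with
the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import yaml

from .errors import ConfigValidationError, ParameterError

__all__ = ["ExperimentConfig", "run_experiment", "config_hash"]

_KINDS = (
    "simulate",
    "gating_test",
    "gating_scan",
    "codebook_scan",
    "bit_relevance",
    "feedback_run",
    "patterns",
)

_CODEBOOKS = {"codebook1", "codebook2", "codebook3", "codebook2+DA"}


@dataclass
class ExperimentConfig:
    kind: str = "simulate"
    circuit: str = "fig1"                    # level name or YAML path
    overrides: Dict[str, object] = field(default_factory=dict)
    engine: str = "simulator"                # simulator | surrogate
    surrogate_weights: Optional[List[float]] = None
    surrogate_bias: float = 0.0
    surrogate_labels: Optional[List[str]] = None
    protocols: List[dict] = field(default_factory=list)
    n_trials: int = 20
    seed: int = 0
    duration_ms: float = 60_000.0
    a_pop: str = "Hcrt"
    b_pop: str = "NE/LC"
    populations: List[str] = field(default_factory=list)
    codebook: str = "codebook3"
    appended_bit: str = "DA"
    delta: float = 0.05
    decision_rule: str = "ci"
    rules: List[dict] = field(default_factory=list)
    wake_threshold_hz: float = 1.5
    out_dir: Optional[str] = None
    save_traces: bool = False

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        violations = []
        if self.kind not in _KINDS:
            violations.append(f"unknown kind {self.kind!r}")
        if self.engine not in ("simulator", "surrogate"):
            violations.append(f"unknown engine {self.engine!r}")
        if self.engine == "surrogate" and self.surrogate_weights is None:
            violations.append("surrogate engine requires surrogate_weights")
        if self.circuit not in ("fig1", "fig2", "fig4", "fig5", "fig6") and not (
            isinstance(self.circuit, str) and os.path.exists(self.circuit)
        ):
            violations.append(f"circuit {self.circuit!r} is neither a level nor a file")
        if self.n_trials < 1:
            violations.append("n_trials must be >= 1")
        if not (0.0 < self.delta < 1.0):
            violations.append("delta must lie in (0, 1)")
        if self.decision_rule not in ("point", "ci"):
            violations.append(f"unknown decision rule {self.decision_rule!r}")
        if self.kind == "gating_test" and self.a_pop == self.b_pop:
            violations.append("gating test needs distinct a_pop and b_pop")
        if self.kind == "codebook_scan" and self.codebook not in _CODEBOOKS:
            violations.append(f"unknown codebook {self.codebook!r}")
        if violations:
            raise ConfigValidationError(violations)

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    @property
    def hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # the output location is not part of the science
        return config_hash(d)


def config_hash(d: dict) -> str:
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# engine / object construction helpers


def _load_circuit(cfg: ExperimentConfig):
    from .circuitry import CircuitGraph, build_circuit

    if cfg.circuit in ("fig1", "fig2", "fig4", "fig5", "fig6"):
        return build_circuit(cfg.circuit, cfg.overrides or None)
    return CircuitGraph.from_yaml(cfg.circuit)


def _surrogate_model(cfg: ExperimentConfig):
    from .surrogate import SurrogateModel

    return SurrogateModel(
        weights=tuple(cfg.surrogate_weights),
        bias=cfg.surrogate_bias,
        labels=tuple(cfg.surrogate_labels or ()),
    )


def _condition_estimator(cfg: ExperimentConfig):
    from .hierarchy import SimulatorEngine, SurrogateEngine

    if cfg.engine == "simulator":
        return SimulatorEngine(_load_circuit(cfg))
    model = _surrogate_model(cfg)
    labels = cfg.surrogate_labels or [f"u{i}" for i in range(len(model.weights))]
    return SurrogateEngine(model, {lb: i for i, lb in enumerate(labels)})

def _parse_protocols(cfg: ExperimentConfig):
    from .optoprotocol import StimProtocol

    return [StimProtocol(**d) for d in cfg.protocols]


def _codebook(name: str):
    from . import codebook as cb

    return {
        "codebook1": cb.CODEBOOK1,
        "codebook2": cb.CODEBOOK2,
        "codebook3": cb.CODEBOOK3,
        "codebook2+DA": cb.CODEBOOK2_PLUS_DA,
    }[name]


def _pattern_estimator(cfg: ExperimentConfig, layout):
    """Forced-bit-pattern estimator: stim for 1, inhibition for 0."""
    from .surrogate import surrogate_estimator

    if cfg.engine == "surrogate":
        model = _surrogate_model(cfg)
        k = len(layout.unit_labels)
        if len(model.weights) > k:
            # weights are declared for the largest layout in play; restrict
            # to the leading unit bits of this codebook
            from .surrogate import SurrogateModel

            model = SurrogateModel(weights=model.weights[:k], bias=model.bias)

        def est(pattern, n, seed):
            return surrogate_estimator(model, pattern, n, seed)

        return est

    from .hierarchy import SimulatorEngine

    sim = SimulatorEngine(_load_circuit(cfg))
    pop_for_bit = {"NE": "NE/LC", "Hcrt": "Hcrt", "His": "His",
                   "ACh": "ACh_BF", "DA": "DA", "5-HT": None}

    def est(pattern, n, seed):
        stim, inhib = [], []
        for label, bit in zip(layout.unit_labels, pattern):
            pop = pop_for_bit.get(label)
            if pop is None:
                raise ParameterError(
                    f"bit {label!r} has no corresponding simulated population"
                )
            (stim if bit else inhib).append(pop)
        return sim(stim, inhib, n, seed)

    return est


# --------------------------------------------------------------------------
# dispatch


def run_experiment(config: ExperimentConfig) -> dict:
    """Validate, run, and (if an output directory is set) persist results."""
    import time

    from . import __version__

    config.validate()
    t_start = time.time()
    result: dict = {
        "kind": config.kind,
        "seed": config.seed,
        "config_hash": config.hash,
        "version": __version__,
    }

    if config.kind == "patterns":
        from .optoprotocol import combinatorial_patterns

        pops = config.populations or ["Hcrt", "NE/LC", "NC"]
        result["patterns"] = combinatorial_patterns(pops)

    elif config.kind == "simulate":
        from . import biophys

        circuit = _load_circuit(config)
        cfg = biophys.SimConfig(
            duration_ms=config.duration_ms,
            wake_threshold_hz=config.wake_threshold_hz,
        )
        trial = biophys.run_trial(circuit, _parse_protocols(config), cfg, config.seed)
        result["timeline"] = trial.timeline.as_dict()
        result["mean_rates_hz"] = {
            name: trial.mean_rate(name) for name in trial.populations
        }
        result["_trial"] = trial

    elif config.kind in ("gating_test", "gating_scan"):
        from .hierarchy import gating_scan, gating_test

        estimator = _condition_estimator(config)
        if config.kind == "gating_test":
            res = gating_test(
                config.a_pop, config.b_pop, estimator,
                n_trials=config.n_trials, seed=config.seed,
                decision_rule=config.decision_rule,
            )
            result["gating"] = res.as_dict()
        else:
            pops = config.populations or ["Hcrt", "NE/LC", "His"]
            scans = gating_scan(
                pops, estimator, n_trials=config.n_trials,
                seed=config.seed, decision_rule=config.decision_rule,
            )
            result["gating_scan"] = [r.as_dict() for r in scans]

    elif config.kind == "codebook_scan":
        from .codebook import estimate_codeword_table

        book = _codebook(config.codebook)
        est = _pattern_estimator(config, book.layout)
        table = estimate_codeword_table(est, book, config.n_trials, config.seed)
        result["table"] = table.as_dict()
        result["_table"] = table

    elif config.kind == "bit_relevance":
        from .codebook import bit_relevance, estimate_codeword_table

        small = _codebook(config.codebook)
        big = _codebook("codebook2+DA" if config.codebook == "codebook2" else config.codebook)
        if small is big:
            raise ConfigValidationError(
                ["bit_relevance needs an extended codebook; use codebook=codebook2"]
            )
        est_s = _pattern_estimator(config, small.layout)
        est_b = _pattern_estimator(config, big.layout)
        t_small = estimate_codeword_table(est_s, small, config.n_trials, config.seed)
        t_big = estimate_codeword_table(est_b, big, config.n_trials, config.seed + 1)
        rd = bit_relevance(t_small, t_big, config.appended_bit, config.delta)
        result["bit_relevance"] = {
            "appended_bit": rd.appended_bit,
            "delta": rd.delta,
            "max_abs_epsilon": rd.max_abs,
            "inconsequential": rd.verdict,
            "epsilons": {"".join(map(str, k)): v for k, v in rd.epsilons.items()},
        }

    elif config.kind == "feedback_run":
        from . import biophys
        from .optoprotocol import (
            ClosedLoopController,
            ControlRule,
            default_stimulation,
            sleep_longer_than,
        )

        circuit = _load_circuit(config)
        rules = []
        for r in config.rules:
            rules.append(
                ControlRule(
                    condition=sleep_longer_than(float(r.get("sleep_longer_than_ms", 30_000.0))),
                    protocol=default_stimulation(
                        r.get("target", "Hcrt"), 0.0, float(r.get("duration_ms", 10_000.0))
                    ),
                    name=r.get("name", ""),
                )
            )
        controller = ClosedLoopController(
            rules, known_populations=[p.name for p in circuit.populations] + ["NC"]
        )
        cfg = biophys.SimConfig(
            duration_ms=config.duration_ms,
            wake_threshold_hz=config.wake_threshold_hz,
        )
        trial = biophys.integrate_network(
            circuit, _parse_protocols(config),
            duration=config.duration_ms, seed=config.seed,
            config=cfg, controller=controller,
        )
        result["timeline"] = trial.timeline.as_dict()
        result["controller_log"] = controller.log
        result["_trial"] = trial

    result["runtime_s"] = round(time.time() - t_start, 3)
    if config.out_dir:
        _persist(config, result)
    return result


def _persist(config: ExperimentConfig, result: dict) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    trial = result.pop("_trial", None)
    table = result.pop("_table", None)
    with open(os.path.join(config.out_dir, "result.json"), "w") as f:
        json.dump(result, f, indent=2, default=str)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    if table is not None:
        table.to_csv(os.path.join(config.out_dir, "table.csv"))
    if trial is not None:
        trial.rates_to_csv(os.path.join(config.out_dir, "rates.csv"))
        if config.save_traces:
            trial.to_hdf5(os.path.join(config.out_dir, "traces.h5"))
            with open(os.path.join(config.out_dir, "trial.json"), "w") as f:
                json.dump(trial.sidecar_json(), f, indent=2, default=str)
    if trial is not None:
        result["_trial"] = trial
    if table is not None:
        result["_table"] = table
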