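"""Circuit topology: populations, signed/scored edges, feedback paths, and
the threshold device that turns an arousal rate signal into a binary
sleep/wake output.

The circuit builders reproduce a sequence of architectures of increasing
complexity:

``fig1``
    hypocretin (Hcrt) and noradrenergic locus-coeruleus (NE/LC) populations,
    10 neurons each;
``fig2``
    50 neurons — adds a pooled local GABAergic population and the
    neocortical (NC) rate unit;
``fig4``
    60 neurons — adds histaminergic (His) neurons and two dedicated
    GABAergic pools (GABA-1 inhibits Hcrt output, GABA-2 inhibits NE/LC
    output);
``fig5``
    adds cholinergic (ACh, basal-forebrain and laterodorsal-tegmental) and
    dopaminergic (DA) populations wired to the neocortex only — a minimal
    placeholder, since their efferent targets within the modeled circuit
    are not established;
``fig6``
    ``fig5`` plus the default +/− edge annotations.

The behavioral sleep-to-wake transition is a node of the graph (so that
edges into it can be annotated) but not a neuron: the transition event
itself is produced by the readout layer.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .biophys import (
    KINETICS,
    NeuronParams,
    PopulationSpec,
    SynapseKinetics,
)
from .errors import ParameterError

__all__ = [
    "TRANSITION",
    "NC",
    "Edge",
    "EdgeAnnotation",
    "NCUnit",
    "ThresholdDevice",
    "CircuitGraph",
    "build_circuit",
    "annotate_edge",
    "apply_placeholder_scores",
    "threshold_device",
    "PLACEHOLDER_SCORES",
]

TRANSITION = "transition"  # the behavioral node
NC = "NC"                  # neocortical rate unit

_LINK = "link"             # edge kind for non-synaptic (rate/behavioral) edges


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    kinetics: Optional[SynapseKinetics] = None
    weight: Optional[float] = None  # rate-unit edges (→NC, NC→, →transition)

    @property
    def kind(self) -> str:
        return self.kinetics.kind if self.kinetics is not None else _LINK

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.source, self.target, self.kind)


@dataclass(frozen=True)
class EdgeAnnotation:
    """Sign (promotes/impedes the transition) and 1–10 strength score."""

    sign: Optional[str] = None
    score: Optional[int] = None

    def __post_init__(self):
        if self.sign is not None and self.sign not in ("+", "-"):
            raise ParameterError("sign must be '+' or '-'")
        if self.score is not None:
            if self.sign is None:
                raise ParameterError("score requires a sign")
            if not (1 <= int(self.score) <= 10):
                raise ParameterError("score must be in 1..10")


@dataclass(frozen=True)
class NCUnit:
    """First-order neocortical rate unit and the two feedback paths.

    The NC rate relaxes toward a weighted sum of afferent population rates
    with time constant ``tau_ms``.  ``state_feedback_gain`` converts the NC
    rate into a depolarizing current onto the Hcrt population (state
    feedback); ``output_feedback_gain`` is an extra drive (Hz) the NC
    receives while the arousal signal reports the wake state (output
    feedback from the transition event).
    """

    tau_ms: float = 1000.0
    weights: Dict[str, float] = field(default_factory=dict)
    state_feedback_gain: float = 0.02
    state_feedback_target: str = "Hcrt"
    output_feedback_gain: float = 0.5


@dataclass(frozen=True)
class ThresholdDevice:
    """Binary output contingent on its input exceeding a threshold.

    Hysteresis: once on, the output stays on until the signal falls below
    ``threshold - hysteresis``.  On-intervals shorter than ``min_dwell_ms``
    are suppressed.
    """

    threshold_hz: float = 1.5
    hysteresis_hz: float = 0.5
    min_dwell_ms: float = 1000.0

    def __post_init__(self):
        if self.threshold_hz <= 0:
            raise ParameterError("threshold must be positive")
        if self.hysteresis_hz < 0 or self.min_dwell_ms < 0:
            raise ParameterError("hysteresis and dwell must be non-negative")


# the signs the shipped default annotation set commits to
_EXPECTED_SIGNS = {
    ("GABA-1", "Hcrt", "fast_gabaa"): "-",
    ("GABA-2", "NE/LC", "fast_gabaa"): "-",
    ("NE/LC", TRANSITION, _LINK): "+",
    ("Hcrt", TRANSITION, _LINK): "+",
}

#: Placeholder 1–10 scores for the four annotated constants of the full
#: circuit diagram.  Empirical scoring is an open research problem; these
#: values only encode the qualitative hierarchy (the NE/LC→transition score
#: exceeds the Hcrt→transition score) and MUST be treated as placeholders.
PLACEHOLDER_SCORES = {
    ("NE/LC", TRANSITION, _LINK): 9,
    ("Hcrt", TRANSITION, _LINK): 6,
    ("GABA-1", "Hcrt", "fast_gabaa"): 7,
    ("GABA-2", "NE/LC", "fast_gabaa"): 5,
}


@dataclass
class CircuitGraph:
    populations: List[PopulationSpec]
    edges: List[Edge]
    nc: Optional[NCUnit] = None
    annotations: Dict[Tuple[str, str, str], EdgeAnnotation] = field(
        default_factory=dict
    )
    level: str = "custom"

    def __post_init__(self):
        names = {p.name for p in self.populations}
        valid = names | {TRANSITION}
        if self.nc is not None:
            valid.add(NC)
        seen = set()
        for e in self.edges:
            if e.source not in valid or e.target not in valid:
                raise ParameterError(f"dangling edge endpoint in {e.key}")
            if e.key in seen:
                raise ParameterError(f"duplicate edge {e.key}")
            seen.add(e.key)
        for key in self.annotations:
            if key not in seen:
                raise ParameterError(f"annotation for missing edge {key}")

    # -- queries ----------------------------------------------------------
    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_names(self) -> List[str]:
        return [p.name for p in self.populations]

    def edge(self, source: str, target: str, kind: str = _LINK) -> Edge:
        for e in self.edges:
            if e.key == (source, target, kind):
                return e
        raise KeyError((source, target, kind))

    def edges_from(self, source: str) -> List[Edge]:
        return [e for e in self.edges if e.source == source]

    def validate_annotations(self) -> List[str]:
        """Flag annotations contradicting the shipped default signs."""
        warnings = []
        for key, expected in _EXPECTED_SIGNS.items():
            ann = self.annotations.get(key)
            if ann is not None and ann.sign is not None and ann.sign != expected:
                warnings.append(
                    f"edge {key[0]}->{key[1]} annotated '{ann.sign}' but the "
                    f"default annotation set assigns '{expected}'"
                )
        return warnings

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def kin_d(k):
            return None if k is None else asdict(k)

        return {
            "level": self.level,
            "populations": [
                {
                    "name": p.name,
                    "size": p.size,
                    "neuron": asdict(p.neuron),
                    "p_intra": p.p_intra,
                    "p_inter": p.p_inter,
                    "jitter": p.jitter,
                }
                for p in self.populations
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "kinetics": kin_d(e.kinetics),
                    "weight": e.weight,
                }
                for e in self.edges
            ],
            "nc": None if self.nc is None else asdict(self.nc),
            "annotations": [
                {"source": s, "target": t, "kind": k,
                 "sign": a.sign, "score": a.score}
                for (s, t, k), a in self.annotations.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitGraph":
        pops = [
            PopulationSpec(
                name=p["name"],
                size=p["size"],
                neuron=NeuronParams(**p["neuron"]),
                p_intra=p.get("p_intra", 0.0),
                p_inter=p.get("p_inter", 0.5),
                jitter=p.get("jitter", 0.05),
            )
            for p in d["populations"]
        ]
        edges = [
            Edge(
                source=e["source"],
                target=e["target"],
                kinetics=None
                if e.get("kinetics") is None
                else SynapseKinetics(**e["kinetics"]),
                weight=e.get("weight"),
            )
            for e in d["edges"]
        ]
        nc = None if d.get("nc") is None else NCUnit(**d["nc"])
        ann = {
            (a["source"], a["target"], a["kind"]): EdgeAnnotation(
                sign=a["sign"], score=a["score"]
            )
            for a in d.get("annotations", [])
        }
        return cls(pops, edges, nc=nc, annotations=ann, level=d.get("level", "custom"))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CircuitGraph":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for p in self.populations:
            g.add_node(p.name, size=p.size, kind="population")
        if self.nc is not None:
            g.add_node(NC, kind="rate_unit")
        g.add_node(TRANSITION, kind="behavioral")
        for e in self.edges:
            ann = self.annotations.get(e.key, EdgeAnnotation())
            g.add_edge(
                e.source,
                e.target,
                kind=e.kind,
                sign=ann.sign or "",
                score=-1 if ann.score is None else int(ann.score),
            )
        nx.write_graphml(g, path)


# --------------------------------------------------------------------------
# builders

def _kin(kind: str, gmax: float, **kw) -> SynapseKinetics:
    return replace(KINETICS[kind], gmax=gmax, **kw)


def _neuron(**kw) -> NeuronParams:
    return NeuronParams(**kw)


# population templates: adaptation strength sets each nucleus' firing regime
_POP_TEMPLATES = {
    "Hcrt": dict(neuron=_neuron(adapt_increment=0.1)),
    "NE/LC": dict(neuron=_neuron(adapt_increment=0.5)),
    "His": dict(neuron=_neuron(adapt_increment=0.3)),
    "GABA": dict(neuron=_neuron(adapt_increment=0.1)),
    "GABA-1": dict(neuron=_neuron(adapt_increment=0.1)),
    "GABA-2": dict(neuron=_neuron(adapt_increment=0.1)),
    "ACh_BF": dict(neuron=_neuron(adapt_increment=0.3)),
    "ACh_LDT": dict(neuron=_neuron(adapt_increment=0.3)),
    "DA": dict(neuron=_neuron(adapt_increment=0.3)),
}


def _pop(name: str, size: int) -> PopulationSpec:
    return PopulationSpec(name=name, size=size, **_POP_TEMPLATES[name])


def _transition_edges(pops) -> List[Edge]:
    promoters = [p for p in pops if not p.startswith("GABA")]
    return [Edge(p, TRANSITION) for p in promoters]


def _nc_edges(nc: NCUnit) -> List[Edge]:
    edges = [Edge(src, NC, weight=w) for src, w in nc.weights.items()]
    edges.append(Edge(NC, nc.state_feedback_target, weight=nc.state_feedback_gain))
    edges.append(Edge(TRANSITION, NC, weight=nc.output_feedback_gain))
    return edges


def _build_fig1() -> CircuitGraph:
    pops = [_pop("Hcrt", 10), _pop("NE/LC", 10)]
    edges = [
        Edge("Hcrt", "NE/LC", _kin("fast_excitatory", 0.02)),
        Edge("Hcrt", "NE/LC", _kin("slow_hcrt", 0.007)),
    ] + _transition_edges(["Hcrt", "NE/LC"])
    return CircuitGraph(pops, edges, level="fig1")


def _build_fig2() -> CircuitGraph:
    pops = [_pop("Hcrt", 20), _pop("NE/LC", 20), _pop("GABA", 10)]
    nc = NCUnit(weights={"NE/LC": 1.0})
    edges = [
        Edge("Hcrt", "NE/LC", _kin("fast_excitatory", 0.02)),
        Edge("Hcrt", "NE/LC", _kin("slow_hcrt", 0.006)),
        Edge("Hcrt", "GABA", _kin("fast_excitatory", 0.6)),
        Edge("NE/LC", "GABA", _kin("fast_excitatory", 0.6)),
        Edge("GABA", "Hcrt", _kin("fast_gabaa", 2.0)),
        Edge("GABA", "NE/LC", _kin("fast_gabaa", 2.0)),
    ] + _transition_edges(["Hcrt", "NE/LC"]) + _nc_edges(nc)
    return CircuitGraph(pops, edges, nc=nc, level="fig2")


def _fig4_core(level: str) -> Tuple[list, list, NCUnit]:
    pops = [
        _pop("Hcrt", 15),
        _pop("NE/LC", 15),
        _pop("His", 10),
        _pop("GABA-1", 10),
        _pop("GABA-2", 10),
    ]
    nc = NCUnit(weights={"NE/LC": 1.0, "His": 0.1})
    edges = [
        Edge("Hcrt", "NE/LC", _kin("fast_excitatory", 0.02)),
        # GABA-1 throttled Hcrt drive: recruitment of NE/LC is marginal, so
        # NE/LC retains veto power over the transition (the gated regime)
        Edge("Hcrt", "NE/LC", _kin("slow_hcrt", 0.0014)),
        Edge("Hcrt", "His", _kin("fast_excitatory", 0.02)),
        Edge("Hcrt", "His", _kin("slow_hcrt", 0.004)),
        Edge("His", "NE/LC", _kin("slow_histamine", 0.004)),
        Edge("His", "Hcrt", _kin("slow_histamine", 0.004)),
        Edge("Hcrt", "GABA-1", _kin("fast_excitatory", 0.6)),
        Edge("NE/LC", "GABA-2", _kin("fast_excitatory", 0.6)),
        Edge("GABA-1", "Hcrt", _kin("fast_gabaa", 0.5)),
        Edge("GABA-2", "NE/LC", _kin("fast_gabaa", 0.5)),
        # slow inhibitory neuropeptide co-release: off by default (gmax 0)
        Edge("GABA-1", "Hcrt", _kin("slow_inhibitory_peptide", 0.0)),
        Edge("GABA-2", "NE/LC", _kin("slow_inhibitory_peptide", 0.0)),
    ]
    edges += _transition_edges(["Hcrt", "NE/LC", "His"])
    return pops, edges, nc


def _build_fig4() -> CircuitGraph:
    pops, edges, nc = _fig4_core("fig4")
    return CircuitGraph(pops, edges + _nc_edges(nc), nc=nc, level="fig4")


def _build_fig5(level: str = "fig5") -> CircuitGraph:
    pops, edges, nc = _fig4_core(level)
    pops += [_pop("ACh_BF", 5), _pop("ACh_LDT", 5), _pop("DA", 5)]
    # ACh/DA efferent wiring within the circuit is not established; they are
    # wired to the neocortical unit only, as flagged placeholders.
    nc = NCUnit(
        weights={"NE/LC": 1.0, "His": 0.1, "ACh_BF": 0.1, "ACh_LDT": 0.1, "DA": 0.1}
    )
    edges += _transition_edges(["ACh_BF", "ACh_LDT", "DA"])
    return CircuitGraph(pops, edges + _nc_edges(nc), nc=nc, level=level)


def _default_annotations(graph: CircuitGraph) -> dict:
    ann = {}
    for e in graph.edges:
        if e.target == TRANSITION:
            ann[e.key] = EdgeAnnotation(sign="+")
        elif e.kinetics is not None:
            if e.kinetics.kind in ("fast_gabaa", "slow_inhibitory_peptide"):
                ann[e.key] = EdgeAnnotation(sign="-")
            else:
                ann[e.key] = EdgeAnnotation(sign="+")
    return ann


def _build_fig6() -> CircuitGraph:
    g = _build_fig5(level="fig6")
    g.annotations = _default_annotations(g)
    return g


_BUILDERS = {
    "fig1": _build_fig1,
    "fig2": _build_fig2,
    "fig4": _build_fig4,
    "fig5": _build_fig5,
    "fig6": _build_fig6,
}


def _apply_override(graph: CircuitGraph, path: str, value) -> None:
    parts = path.split(".")
    try:
        if parts[0] == "populations":
            name = parts[1]
            idx = graph.population_names.index(name)
            p = graph.populations[idx]
            if parts[2] == "neuron":
                neuron = replace(p.neuron, **{parts[3]: value})
                graph.populations[idx] = replace(p, neuron=neuron)
            else:
                graph.populations[idx] = replace(p, **{parts[2]: value})
        elif parts[0] == "edges":
            src, tgt = parts[1].split("->")
            kind = parts[2]
            e = graph.edge(src, tgt, kind)
            i = graph.edges.index(e)
            if kind == _LINK:
                graph.edges[i] = replace(e, **{parts[3]: value})
            else:
                graph.edges[i] = replace(
                    e, kinetics=replace(e.kinetics, **{parts[3]: value})
                )
        elif parts[0] == "nc":
            if graph.nc is None:
                raise ParameterError("circuit has no NC unit")
            graph.nc = replace(graph.nc, **{parts[1]: value})
        elif parts[0] == "noise":
            # convenience: set the noise amplitude of every population
            for i, p in enumerate(graph.populations):
                graph.populations[i] = replace(
                    p, neuron=replace(p.neuron, noise_amplitude=value)
                )
        else:
            raise KeyError(parts[0])
    except (KeyError, IndexError, ValueError, TypeError) as exc:
        raise ParameterError(f"unknown override {path!r}") from exc


def build_circuit(level: str, overrides: Optional[dict] = None) -> CircuitGraph:
    """Build one of the predefined circuit architectures.

    ``overrides`` maps dotted parameter paths to replacement values, e.g.
    ``{"populations.Hcrt.size": 12}``,
    ``{"edges.Hcrt->NE/LC.slow_hcrt.gmax": 0.012}``, ``{"noise": 0.0}``.
    Unknown levels or paths raise :class:`ParameterError`.
    """
    if level not in _BUILDERS:
        raise ParameterError(
            f"unknown circuit level {level!r}; choose from {sorted(_BUILDERS)}"
        )
    graph = _BUILDERS[level]()
    for path, value in (overrides or {}).items():
        _apply_override(graph, path, value)
    return graph


def annotate_edge(
    graph: CircuitGraph, edge_key: Tuple[str, str, str], annotation: EdgeAnnotation
) -> CircuitGraph:
    """Return a copy of the graph with the annotation attached.

    Annotations contradicting the shipped default signs are accepted but
    flagged by :meth:`CircuitGraph.validate_annotations`.
    """
    keys = {e.key for e in graph.edges}
    if tuple(edge_key) not in keys:
        raise ParameterError(f"no such edge {edge_key}")
    out = copy.deepcopy(graph)
    out.annotations[tuple(edge_key)] = annotation
    return out


def apply_placeholder_scores(graph: CircuitGraph) -> CircuitGraph:
    """Attach the documented placeholder scores to the annotated constants."""
    out = copy.deepcopy(graph)
    for key, score in PLACEHOLDER_SCORES.items():
        if key in {e.key for e in out.edges}:
            ann = out.annotations.get(key, EdgeAnnotation(sign="+"))
            out.annotations[key] = EdgeAnnotation(sign=ann.sign, score=score)
    return out


# --------------------------------------------------------------------------
# threshold device

def threshold_device(
    signal: np.ndarray, device: ThresholdDevice, step_ms: float = 1.0
) -> np.ndarray:
    """Binary output of the threshold device applied to a rate signal.

    Pointwise ``signal > threshold`` with hysteresis (release at
    ``threshold - hysteresis``) followed by suppression of on-runs shorter
    than the minimum dwell.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ParameterError("signal must be non-empty")
    out = np.zeros(x.size, dtype=np.int8)
    on = False
    lo = device.threshold_hz - device.hysteresis_hz
    for i, v in enumerate(x):
        if on:
            on = v > lo  # strict: zero hysteresis degenerates to pointwise >
        else:
            on = v > device.threshold_hz
        out[i] = 1 if on else 0
    if device.min_dwell_ms > 0:
        min_len = int(np.ceil(device.min_dwell_ms / step_ms))
        i = 0
        n = out.size
        while i < n:
            if out[i] == 1:
                j = i
                while j < n and out[j] == 1:
                    j += 1
                if j - i < min_len:
                    out[i:j] = 0
                i = j
            else:
                i += 1
    return out
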