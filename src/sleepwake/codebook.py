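"""Binary codebook formalism for redundancy among arousal circuits.

A codeword is a binary vector whose least-significant bit (LSB, stored
last) is the behavioral state — 1 for wake, 0 for sleep — and whose
remaining "unit bits" record whether a neuromodulatory population's firing
rate exceeds a per-unit threshold.  The 7-bit codebook orders the unit bits
by decreasing perceived hierarchy: NE, ACh, DA, Hcrt, 5-HT, His.  The bit
order is data, not code: it is expected to be rearranged as hierarchy
experiments accumulate.

The formalism supports: enumeration, conditional wake-probability tables
P[LSB=1 | unit pattern], probabilistic dominance between comparable
codewords, dominance closure over free bits (codebook "structure"),
redundancy degree, minimum Hamming distance, and ε-based relevance of an
appended bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ComparabilityError, ParameterError
from .readout import TransitionEstimate

__all__ = [
    "STATE",
    "BitLayout",
    "Codeword",
    "Codebook",
    "BitThresholds",
    "CodewordProbabilityTable",
    "RedundancyDelta",
    "CODEBOOK1",
    "CODEBOOK2",
    "CODEBOOK3",
    "CODEBOOK2_PLUS_DA",
    "CODEBOOK_FAMILY",
    "enumerate_codebook",
    "unit_patterns",
    "binarize_state",
    "estimate_codeword_table",
    "comparable",
    "codeword_probability",
    "dominates",
    "dominance_closure",
    "min_hamming_distance",
    "redundancy_degree",
    "bit_relevance",
]

STATE = "state"  # the LSB label


@dataclass(frozen=True)
class BitLayout:
    """Ordered bit labels; the LSB (behavioral state) is last."""

    labels: Tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.labels.count(STATE) != 1:
            raise ParameterError("layout must contain the state bit exactly once")
        if self.labels[-1] != STATE:
            raise ParameterError("the state bit must be the LSB (last position)")
        if len(self.labels) < 2:
            raise ParameterError("layout needs at least one unit bit plus the LSB")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("duplicate bit labels")

    @property
    def unit_labels(self) -> Tuple[str, ...]:
        return self.labels[:-1]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Codeword:
    bits: Tuple[int, ...]
    layout: BitLayout

    def __post_init__(self):
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if any(b not in (0, 1) for b in self.bits):
            raise ParameterError("bits must be 0/1")
        if len(self.bits) != len(self.layout):
            raise ParameterError("bit count must match the layout")

    @property
    def lsb(self) -> int:
        return self.bits[-1]

    @property
    def unit_bits(self) -> Tuple[int, ...]:
        return self.bits[:-1]

    def bit(self, label: str) -> int:
        return self.bits[self.layout.labels.index(label)]

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


@dataclass(frozen=True)
class Codebook:
    """The complete family of binary vectors over a layout."""

    layout: BitLayout
    name: str = "custom"

    @property
    def codewords(self) -> List[Codeword]:
        return [
            Codeword(bits, self.layout)
            for bits in itertools.product((0, 1), repeat=len(self.layout))
        ]

    def __len__(self) -> int:
        return 2 ** len(self.layout)


CODEBOOK1 = Codebook(
    BitLayout(("NE", "ACh", "DA", "Hcrt", "5-HT", "His", STATE)), name="codebook1"
)
CODEBOOK2 = Codebook(BitLayout(("NE", "ACh", STATE)), name="codebook2")
CODEBOOK3 = Codebook(BitLayout(("NE", STATE)), name="codebook3")
#: Codebook #2 with DA appended as B3 — the worked redundancy example.
CODEBOOK2_PLUS_DA = Codebook(BitLayout(("NE", "ACh", "DA", STATE)), name="codebook2+DA")
#: The enumerated codeword family (7-, 3- and 2-bit books).
CODEBOOK_FAMILY = (CODEBOOK1, CODEBOOK2, CODEBOOK3)


def enumerate_codebook(layout: BitLayout) -> Codebook:
    """All 2^n codewords of a layout, lexicographic, no duplicates."""
    if not isinstance(layout, BitLayout):
        layout = BitLayout(tuple(layout))
    return Codebook(layout)


def unit_patterns(layout: BitLayout) -> List[Tuple[int, ...]]:
    """All non-LSB bit patterns of a layout, lexicographic."""
    return list(itertools.product((0, 1), repeat=len(layout) - 1))


# --------------------------------------------------------------------------
# bit assignment


@dataclass(frozen=True)
class BitThresholds:
    """Per-unit firing-rate thresholds (Hz) for declaring a bit 1.

    The threshold is the collective population rate required to declare the
    circuit "stimulated"; values are species- and preparation-dependent
    config inputs, not constants of the model.
    """

    thresholds_hz: Dict[str, float]

    def __post_init__(self):
        for label, th in self.thresholds_hz.items():
            if th <= 0:
                raise ParameterError(f"threshold for {label!r} must be positive")

    def get(self, label: str) -> float:
        if label not in self.thresholds_hz:
            raise ParameterError(f"missing rate threshold for bit {label!r}")
        return self.thresholds_hz[label]


def binarize_state(
    rates_hz: Dict[str, float],
    thresholds: BitThresholds,
    vigilance: str,
    layout: BitLayout = CODEBOOK1.layout,
) -> Codeword:
    """Codeword from population rates at a decision time plus the state.

    A unit bit is 1 iff its rate strictly exceeds its threshold (a rate
    exactly at threshold yields 0); the LSB is 1 iff vigilance is wake.
    """
    bits = []
    for label in layout.unit_labels:
        if label not in rates_hz:
            raise ParameterError(f"missing rate for bit {label!r}")
        bits.append(1 if rates_hz[label] > thresholds.get(label) else 0)
    bits.append(1 if vigilance == "wake" else 0)
    return Codeword(tuple(bits), layout)


# --------------------------------------------------------------------------
# probability tables


@dataclass
class CodewordProbabilityTable:
    """P[LSB=1 | unit pattern] for every pattern of a layout."""

    layout: BitLayout
    entries: Dict[Tuple[int, ...], TransitionEstimate]

    def __post_init__(self):
        expected = set(unit_patterns(self.layout))
        if set(self.entries) != expected:
            raise ParameterError("table must contain every unit pattern exactly once")

    def p(self, pattern: Sequence[int]) -> float:
        return self.entries[tuple(pattern)].p_hat

    def estimate(self, pattern: Sequence[int]) -> TransitionEstimate:
        return self.entries[tuple(pattern)]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for pattern in unit_patterns(self.layout):
            est = self.entries[pattern]
            row = dict(zip(self.layout.unit_labels, pattern))
            row.update(
                p_hat=est.p_hat, ci_low=est.ci_low, ci_high=est.ci_high,
                n_trials=est.n_trials,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def as_dict(self) -> dict:
        return {
            "layout": list(self.layout.labels),
            "entries": [
                {"pattern": list(k), **v.as_dict()} for k, v in self.entries.items()
            ],
        }


PatternEstimator = Callable[[Tuple[int, ...], int, int], TransitionEstimate]


def estimate_codeword_table(
    estimator: PatternEstimator,
    codebook: Codebook,
    n_trials: int,
    seed: int = 0,
) -> CodewordProbabilityTable:
    """Estimate P[LSB=1 | pattern] for every pattern of a codebook.

    ``estimator(pattern, n_trials, seed)`` realizes the forced bit pattern
    (stimulation for 1, inhibition for 0) and returns a
    :class:`TransitionEstimate`.  Deterministic given ``seed``: pattern i
    uses seed ``seed + i·n_trials``.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    entries = {}
    for i, pattern in enumerate(unit_patterns(codebook.layout)):
        entries[pattern] = estimator(pattern, n_trials, seed + i * n_trials)
    return CodewordProbabilityTable(layout=codebook.layout, entries=entries)


# --------------------------------------------------------------------------
# dominance


def comparable(c1: Codeword, c2: Codeword) -> bool:
    """Whether probabilistic dominance between two codewords is meaningful.

    Codewords with different unit bits *and* different LSBs describe both a
    different perturbation and a different induced state; comparing them is
    not sensible.
    """
    if c1.layout != c2.layout:
        raise ParameterError("codewords have different layouts")
    return c1.lsb == c2.lsb or c1.unit_bits == c2.unit_bits


def codeword_probability(c: Codeword, table: CodewordProbabilityTable):
    """P[C] and its interval: the table's conditional for LSB=1 codewords,
    its complement for LSB=0 codewords."""
    est = table.estimate(c.unit_bits)
    if c.lsb == 1:
        return est.p_hat, est.ci_low, est.ci_high
    return 1.0 - est.p_hat, 1.0 - est.ci_high, 1.0 - est.ci_low


def dominates(
    c1: Codeword,
    c2: Codeword,
    table: CodewordProbabilityTable,
    decision_rule: str = "ci",
) -> bool:
    """C1 probabilistically dominates C2: P[C1] > P[C2].

    Incomparable pairs raise :class:`ComparabilityError` (dominance is
    undefined, not false).  Under the ``ci`` rule the two Wilson intervals
    must be disjoint; equality is never dominance.
    """
    if not comparable(c1, c2):
        raise ComparabilityError(
            f"codewords {c1} and {c2} differ in both unit bits and LSB"
        )
    p1, lo1, hi1 = codeword_probability(c1, table)
    p2, lo2, hi2 = codeword_probability(c2, table)
    if decision_rule == "point":
        return p1 > p2
    if decision_rule == "ci":
        return lo1 > hi2
    raise ParameterError(f"unknown decision rule {decision_rule!r}")


def dominance_closure(
    dominant: Codeword,
    dominated: Codeword,
    free_bits: Iterable[str],
) -> List[Codeword]:
    """The codeword family a single dominance relation extends to.

    Returns every codeword agreeing with ``dominated`` on its fixed unit
    bits and LSB while the ``free_bits`` vary over all 2^|free| values.
    """
    free = list(free_bits)
    layout = dominated.layout
    for label in free:
        if label not in layout.unit_labels:
            raise ParameterError(f"free bit {label!r} not a unit bit of the layout")
    if len(set(free)) != len(free):
        raise ParameterError("duplicate free bits")
    positions = [layout.labels.index(lb) for lb in free]
    out = []
    for values in itertools.product((0, 1), repeat=len(free)):
        bits = list(dominated.bits)
        for pos, v in zip(positions, values):
            bits[pos] = v
        out.append(Codeword(tuple(bits), layout))
    return out


def min_hamming_distance(codebook_or_words) -> int:
    """Minimum pairwise Hamming distance of a codebook.

    Accepts a :class:`Codebook` (full enumeration ⇒ distance 1 for any
    layout) or an explicit collection of codewords / bit tuples.
    """
    if isinstance(codebook_or_words, Codebook):
        # adjacent codewords of a full binary codebook differ in one bit
        words = [w.bits for w in codebook_or_words.codewords]
    else:
        words = [
            tuple(w.bits) if isinstance(w, Codeword) else tuple(int(b) for b in w)
            for w in codebook_or_words
        ]
    if len(words) < 2:
        raise ParameterError("need at least two codewords")
    arr = np.asarray(words, dtype=np.int8)
    best = arr.shape[1] + 1
    for i in range(len(arr) - 1):
        d = np.abs(arr[i + 1:] - arr[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 1:
                return 1
    return best


def redundancy_degree(codebook: Codebook) -> int:
    """Number of binary positions incorporated in inducing the state.

    This is the codeword bit-length (unit bits + the behavioral bit) — a
    deliberately non-coding-theoretic definition: the full binary codebook
    has no redundancy in the error-correcting sense.
    """
    return len(codebook.layout)


# --------------------------------------------------------------------------
# ε-based relevance of an appended bit


@dataclass(frozen=True)
class RedundancyDelta:
    """Per-pattern ε adjustments when a codebook gains one unit bit."""

    epsilons: Dict[Tuple[int, ...], float]
    delta: float
    appended_bit: str

    @property
    def max_abs(self) -> float:
        return max(abs(e) for e in self.epsilons.values())

    @property
    def verdict(self) -> bool:
        """True iff the appended bit is inconsequential (all |ε| < δ)."""
        return self.max_abs < self.delta


def bit_relevance(
    table_k: CodewordProbabilityTable,
    table_k1: CodewordProbabilityTable,
    appended_bit: str,
    delta: float = 0.05,
) -> RedundancyDelta:
    """ε-adjustments of the wake probabilities after appending one bit.

    ε_i = P_{k+1}[LSB=1 | extended pattern i] − P_k[LSB=1 | restriction];
    the appended bit is deemed inconsequential when every |ε_i| < δ.
    δ must lie in the open interval (0, 1).
    """
    if not (0.0 < delta < 1.0):
        raise ParameterError("delta must lie in (0, 1)")
    small = table_k.layout.unit_labels
    big = table_k1.layout.unit_labels
    if appended_bit not in big or set(big) - {appended_bit} != set(small) or len(
        big
    ) != len(small) + 1:
        raise ParameterError(
            "extended layout must equal the base layout plus the appended bit"
        )
    pos = {lb: i for i, lb in enumerate(big)}
    eps = {}
    for pattern in unit_patterns(table_k1.layout):
        restriction = tuple(pattern[pos[lb]] for lb in small)
        eps[pattern] = table_k1.p(pattern) - table_k.p(restriction)
    return RedundancyDelta(epsilons=eps, delta=delta, appended_bit=appended_bit)
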