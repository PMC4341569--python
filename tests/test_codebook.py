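"""Codebook formalism: enumeration, dominance, structure, redundancy."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepwake import (
    CODEBOOK1,
    CODEBOOK2,
    CODEBOOK2_PLUS_DA,
    CODEBOOK3,
    BitLayout,
    BitThresholds,
    Codebook,
    Codeword,
    ComparabilityError,
    ParameterError,
    SurrogateModel,
    binarize_state,
    bit_relevance,
    brute_force_table,
    comparable,
    dominance_closure,
    dominates,
    enumerate_codebook,
    min_hamming_distance,
    redundancy_degree,
)
from sleepwake.codebook import estimate_codeword_table, unit_patterns
from sleepwake.surrogate import surrogate_estimator


class TestEnumeration:
    @pytest.mark.parametrize(
        "book,expected",
        [(CODEBOOK1, 128), (CODEBOOK2, 8), (CODEBOOK3, 4), (CODEBOOK2_PLUS_DA, 16)],
    )
    def test_codeword_counts(self, book, expected):
        words = book.codewords
        assert len(words) == expected
        assert len(set(w.bits for w in words)) == expected  # no duplicates

    def test_lexicographic_order(self):
        words = enumerate_codebook(BitLayout(("NE", "ACh", "state"))).codewords
        as_ints = [int(str(w), 2) for w in words]
        assert as_ints == list(range(8))

    def test_layout_requires_lsb(self):
        with pytest.raises(ParameterError):
            BitLayout(("NE", "ACh"))
        with pytest.raises(ParameterError):
            BitLayout(("state", "NE"))  # LSB must be last

    def test_codeword_validation(self):
        with pytest.raises(ParameterError):
            Codeword((0, 2), CODEBOOK3.layout)
        with pytest.raises(ParameterError):
            Codeword((0, 1, 0), CODEBOOK3.layout)


class TestBinarize:
    THRESH = BitThresholds(
        {lb: 1.0 for lb in CODEBOOK1.layout.unit_labels}
    )

    def test_all_quiet_sleep_is_zero(self):
        rates = {lb: 0.0 for lb in CODEBOOK1.layout.unit_labels}
        w = binarize_state(rates, self.THRESH, "sleep")
        assert str(w) == "0000000"

    def test_ne_active_wake(self):
        rates = {lb: 0.0 for lb in CODEBOOK1.layout.unit_labels}
        rates["NE"] = 3.0
        w = binarize_state(rates, self.THRESH, "wake")
        assert str(w) == "1000001"

    def test_threshold_is_strict(self):
        rates = {lb: 1.0 for lb in CODEBOOK1.layout.unit_labels}  # exactly at
        w = binarize_state(rates, self.THRESH, "sleep")
        assert str(w) == "0000000"

    def test_missing_rate_errors(self):
        with pytest.raises(ParameterError):
            binarize_state({"NE": 2.0}, self.THRESH, "wake")


class TestComparability:
    L = CODEBOOK1.layout

    def test_different_units_and_lsb_incomparable(self):
        c2 = Codeword((1, 0, 1, 1, 0, 1, 0), self.L)
        c3 = Codeword((1, 1, 1, 1, 1, 1, 1), self.L)
        assert not comparable(c2, c3)

    def test_identical_comparable(self):
        c = Codeword((1, 0, 1, 1, 0, 0, 1), self.L)
        assert comparable(c, c)

    def test_same_units_different_lsb_comparable(self):
        a = Codeword((1, 0, 1, 1, 0, 0, 1), self.L)
        b = Codeword((1, 0, 1, 1, 0, 0, 0), self.L)
        assert comparable(a, b)

    def test_layout_mismatch_errors(self):
        with pytest.raises(ParameterError):
            comparable(
                Codeword((0, 1), CODEBOOK3.layout),
                Codeword((0, 0, 1), CODEBOOK2.layout),
            )


@pytest.fixture
def exact_table3():
    """Closed-form table on the 3-bit codebook, monotone positive weights."""
    model = SurrogateModel(weights=(2.0, 1.0), bias=-1.0)
    return brute_force_table(model, CODEBOOK2)


class TestDominance:
    def test_strict_comparison(self, exact_table3):
        hi = Codeword((1, 1, 1), CODEBOOK2.layout)
        lo = Codeword((0, 0, 1), CODEBOOK2.layout)
        assert dominates(hi, lo, exact_table3)
        assert not dominates(lo, hi, exact_table3)

    def test_equal_probabilities_not_dominant(self, exact_table3):
        c = Codeword((1, 0, 1), CODEBOOK2.layout)
        assert not dominates(c, c, exact_table3)

    def test_incomparable_raises(self, exact_table3):
        a = Codeword((1, 0, 1), CODEBOOK2.layout)
        b = Codeword((0, 1, 0), CODEBOOK2.layout)
        with pytest.raises(ComparabilityError):
            dominates(a, b, exact_table3)

    def test_strict_partial_order_per_comparability_class(self, exact_table3):
        """Irreflexive and transitive over every comparable codeword pair."""
        words = CODEBOOK2.codewords
        for c in words:
            assert not dominates(c, c, exact_table3, decision_rule="point")
        for x, y, z in itertools.product(words, repeat=3):
            if not (comparable(x, y) and comparable(y, z) and comparable(x, z)):
                continue
            if dominates(x, y, exact_table3, "point") and dominates(
                y, z, exact_table3, "point"
            ):
                assert dominates(x, z, exact_table3, "point")

    def test_monotone_weights_give_superset_dominance(self, exact_table3):
        """Adding wake-promoting activity cannot lower the wake probability."""
        layout = CODEBOOK2.layout
        for u1 in unit_patterns(layout):
            for u2 in unit_patterns(layout):
                strict_superset = all(a >= b for a, b in zip(u1, u2)) and u1 != u2
                if strict_superset:
                    c1 = Codeword(u1 + (1,), layout)
                    c2 = Codeword(u2 + (1,), layout)
                    assert dominates(c1, c2, exact_table3, "point")


class TestClosure:
    def test_reference_closure_cardinality(self):
        layout = CODEBOOK1.layout
        dominant = Codeword((1, 0, 1, 1, 0, 0, 1), layout)
        dominated = Codeword((0, 0, 0, 0, 0, 0, 1), layout)
        free = ("ACh", "DA", "His", "Hcrt", "5-HT")
        family = dominance_closure(dominant, dominated, free)
        assert len(family) == 32
        assert len(set(w.bits for w in family)) == 32
        for w in family:
            assert w.lsb == dominated.lsb
            assert w.bit("NE") == dominated.bit("NE")

    def test_zero_free_bits(self):
        layout = CODEBOOK2.layout
        d = Codeword((1, 0, 1), layout)
        assert dominance_closure(d, d, ()) == [d]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_small_closures(self, k):
        layout = CODEBOOK1.layout
        d = Codeword((0,) * 7, layout)
        free = layout.unit_labels[:k]
        assert len(dominance_closure(d, d, free)) == 2**k

    def test_cardinality_exhaustive_over_subsets(self):
        """|closure| = 2^|free| for every free-bit subset up to size 5."""
        layout = CODEBOOK1.layout
        d = Codeword((1, 0, 0, 1, 0, 0, 0), layout)
        for k in range(6):
            for free in itertools.combinations(layout.unit_labels, k):
                fam = dominance_closure(d, d, free)
                assert len(fam) == 2**k
                assert len(set(w.bits for w in fam)) == 2**k

    def test_unknown_free_bit_errors(self):
        d = Codeword((0, 0), CODEBOOK3.layout)
        with pytest.raises(ParameterError):
            dominance_closure(d, d, ("DA",))


class TestDistanceAndRedundancy:
    def test_full_codebook_min_distance_is_one(self):
        assert min_hamming_distance(CODEBOOK1) == 1

    def test_repetition_code(self):
        assert min_hamming_distance([(0, 0, 0), (1, 1, 1)]) == 3

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_any_full_codebook_distance_one(self, n):
        words = list(itertools.product((0, 1), repeat=n))
        assert min_hamming_distance(words) == 1

    def test_too_few_codewords(self):
        with pytest.raises(ParameterError):
            min_hamming_distance([(0, 1)])

    @pytest.mark.parametrize(
        "book,deg",
        [(CODEBOOK1, 7), (CODEBOOK2, 3), (CODEBOOK3, 2), (CODEBOOK2_PLUS_DA, 4)],
    )
    def test_redundancy_degree(self, book, deg):
        assert redundancy_degree(book) == deg


class TestEstimatedTables:
    def test_monte_carlo_matches_closed_form(self):
        model = SurrogateModel(weights=(1.5, -0.5), bias=0.2)
        est = lambda pattern, n, seed: surrogate_estimator(model, pattern, n, seed)
        table = estimate_codeword_table(est, CODEBOOK2, n_trials=4000, seed=7)
        for pattern in unit_patterns(CODEBOOK2.layout):
            p_true = model.probability(pattern)
            e = table.estimate(pattern)
            assert e.ci_low <= p_true <= e.ci_high

    def test_codebook3_has_two_entries(self):
        model = SurrogateModel(weights=(1.0,))
        est = lambda pattern, n, seed: surrogate_estimator(model, pattern, n, seed)
        table = estimate_codeword_table(est, CODEBOOK3, n_trials=10, seed=0)
        assert len(table.entries) == 2

    def test_zero_trials_errors(self):
        model = SurrogateModel(weights=(1.0,))
        est = lambda pattern, n, seed: surrogate_estimator(model, pattern, n, seed)
        with pytest.raises(ParameterError):
            estimate_codeword_table(est, CODEBOOK3, n_trials=0, seed=0)

    def test_deterministic_given_seed(self):
        model = SurrogateModel(weights=(1.0, 0.5), bias=0.0)
        est = lambda pattern, n, seed: surrogate_estimator(model, pattern, n, seed)
        t1 = estimate_codeword_table(est, CODEBOOK2, n_trials=100, seed=3)
        t2 = estimate_codeword_table(est, CODEBOOK2, n_trials=100, seed=3)
        assert all(
            t1.p(p) == t2.p(p) for p in unit_patterns(CODEBOOK2.layout)
        )

    def test_table_round_trips_to_dataframe(self):
        model = SurrogateModel(weights=(1.0,))
        table = brute_force_table(model, CODEBOOK3)
        df = table.to_dataframe()
        assert len(df) == 2
        assert set(["NE", "p_hat", "ci_low", "ci_high"]).issubset(df.columns)


class TestBitRelevance:
    BASE = SurrogateModel(weights=(2.0, 1.0), bias=-1.0)

    def _tables(self, w_appended):
        ext = SurrogateModel(weights=(2.0, 1.0, w_appended), bias=-1.0)
        return (
            brute_force_table(self.BASE, CODEBOOK2),
            brute_force_table(ext, CODEBOOK2_PLUS_DA),
        )

    def test_null_appended_bit_is_inconsequential(self):
        tk, tk1 = self._tables(0.0)
        rd = bit_relevance(tk, tk1, "DA", delta=0.05)
        assert rd.max_abs == 0.0
        assert rd.verdict
        assert len(rd.epsilons) == 8

    def test_heavy_appended_bit_is_consequential(self):
        tk, tk1 = self._tables(3.0)
        rd = bit_relevance(tk, tk1, "DA", delta=0.05)
        assert rd.max_abs > 0.05
        assert not rd.verdict

    def test_epsilons_match_closed_form(self):
        w = 1.2
        tk, tk1 = self._tables(w)
        ext = SurrogateModel(weights=(2.0, 1.0, w), bias=-1.0)
        rd = bit_relevance(tk, tk1, "DA", delta=0.5)
        for pattern, eps in rd.epsilons.items():
            expected = ext.probability(pattern) - self.BASE.probability(pattern[:2])
            assert eps == pytest.approx(expected, abs=1e-12)

    def test_restriction_consistency(self):
        """Zero-weight appended bit: the extended table marginalizes back."""
        tk, tk1 = self._tables(0.0)
        for pattern in unit_patterns(CODEBOOK2_PLUS_DA.layout):
            assert tk1.p(pattern) == pytest.approx(tk.p(pattern[:2]), abs=1e-15)

    @pytest.mark.parametrize("bad_delta", [0.0, 1.0, -0.1])
    def test_delta_open_interval(self, bad_delta):
        tk, tk1 = self._tables(0.0)
        with pytest.raises(ParameterError):
            bit_relevance(tk, tk1, "DA", delta=bad_delta)

    def test_layout_mismatch_errors(self):
        tk, _ = self._tables(0.0)
        with pytest.raises(ParameterError):
            bit_relevance(tk, tk, "DA", delta=0.05)


@given(st.integers(min_value=2, max_value=6))
def test_enumeration_cardinality_property(n):
    layout = BitLayout(tuple(f"u{i}" for i in range(n - 1)) + ("state",))
    book = enumerate_codebook(layout)
    assert len(book) == 2**n
    assert redundancy_degree(book) == n
    assert min_hamming_distance(book) == 1
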