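"""Unit and property tests for the disagreement kernel and IBMD estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibmd import (
    DataError,
    NoComparablePairsError,
    RatingsTable,
    ibmd,
    ibmd_two_observer,
    pair_disagreement,
)
from oracles import naive_ibmd

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    ("x", "y", "expected"),
    [
        (80.0, 80.0, 0.0),            # identical readings
        (0.0, 5.0, 1.0),              # one observer reports zero: maximal
        (5.0, 0.0, 1.0),
        (0.0, 0.0, 0.0),              # the 0/0 convention
        (65.0, 70.0, 0.09953567355091437),  # log2(5/70 + 1), frozen closed form
    ],
)
def test_pair_kernel_known_values(x, y, expected):
    assert pair_disagreement(x, y) == pytest.approx(expected, abs=1e-12)


def test_pair_kernel_rejects_negative_values():
    with pytest.raises(DataError, match="-3"):
        pair_disagreement(-3.0, 1.0)
    with pytest.raises(DataError):
        pair_disagreement(1.0, -0.5)


def test_pair_kernel_metric_axioms_on_random_triples():
    """Symmetry, identity of indiscernibles and the triangle inequality on
    ten thousand random triples in (0, 100]."""
    rng = np.random.default_rng(42)
    triples = rng.uniform(1e-9, 100.0, size=(10_000, 3))
    for x, y, z in triples:
        dxy = pair_disagreement(x, y)
        dyz = pair_disagreement(y, z)
        dxz = pair_disagreement(x, z)
        assert dxy == pair_disagreement(y, x)
        assert dxy >= 0.0
        assert dxz <= dxy + dyz + 1e-12
    assert pair_disagreement(3.7, 3.7) == 0.0


def test_ibmd_perfect_agreement_is_zero():
    table = RatingsTable.from_rows([[5, 5, 5], [0, 0], [7.2, 7.2, 7.2, 7.2]])
    assert ibmd(table).ibmd == 0.0


def test_ibmd_zero_only_under_perfect_agreement(random_rows):
    rows = random_rows(6, seed=1)
    rows[3][0] += 0.5  # ensure at least one discordant pair
    assert ibmd(RatingsTable.from_rows(rows)).ibmd > 0.0


def test_ibmd_matches_brute_force_oracle_on_small_tables():
    """Estimator equals an independently coded double-loop sum on every
    random table with up to 4 cases and 4 observers."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 5))
        rows = [
            rng.uniform(0.0, 50.0, size=int(rng.integers(2, 5))).tolist()
            for _ in range(n)
        ]
        est = ibmd(RatingsTable.from_rows(rows))
        assert est.ibmd == pytest.approx(naive_ibmd(rows), abs=1e-14)
        assert est.n_pairs_total == sum(len(r) * (len(r) - 1) // 2 for r in rows)


def test_ibmd_range_and_bookkeeping(random_rows):
    rows = random_rows(12, seed=3, allow_zero=True)
    est = ibmd(RatingsTable.from_rows(rows + [[4.0], []]))
    assert 0.0 <= est.ibmd <= 1.0
    assert est.n_cases_used == 12
    assert est.n_cases_dropped == 2


def test_ibmd_errors_without_comparable_pairs():
    with pytest.raises(NoComparablePairsError):
        ibmd(RatingsTable.from_rows([[1.0], [2.0]]))


def test_negative_observation_rejected_at_table_construction():
    with pytest.raises(DataError, match="negative"):
        RatingsTable.from_rows([[1.0, -2.0]])


@settings(max_examples=100, derandomize=True)
@given(
    rows=st.lists(
        st.lists(positive, min_size=2, max_size=5), min_size=1, max_size=6
    ),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_scale_invariance(rows, scale):
    """Multiplying every observation by c > 0 leaves IBMD unchanged."""
    base = ibmd(RatingsTable.from_rows(rows)).ibmd
    scaled = ibmd(
        RatingsTable.from_rows([[scale * v for v in r] for r in rows])
    ).ibmd
    assert scaled == pytest.approx(base, abs=1e-12)
    assert 0.0 <= base <= 1.0


def test_permutation_invariance_bit_for_bit(random_rows):
    rows = random_rows(10, seed=11)
    rng = np.random.default_rng(0)
    shuffled = [list(rng.permutation(r)) for r in rows]
    rng.shuffle(shuffled)
    a = ibmd(RatingsTable.from_rows(rows)).ibmd
    b = ibmd(RatingsTable.from_rows(shuffled)).ibmd
    assert a == b  # exact summation makes this bitwise


def test_two_observer_formula_known_values():
    assert ibmd_two_observer([(1, 1), (2, 2)]) == 0.0
    assert ibmd_two_observer([(0, 5)]) == 1.0
    with pytest.raises(DataError):
        ibmd_two_observer([])


def test_generalized_estimator_reduces_to_two_observer(maternal_groups):
    """On all-M_i=2 data the generalized estimator and the original
    two-observer formula agree to machine precision (distinct code paths)."""
    initial = maternal_groups["initial"]
    pairs = [(c.values[0], c.values[1]) for c in initial]
    two_col = RatingsTable.from_rows([[x, y] for x, y in pairs])
    assert ibmd_two_observer(pairs) == ibmd(two_col).ibmd

    rng = np.random.default_rng(5)
    pairs = [tuple(rng.uniform(0, 10, 2)) for _ in range(17)]
    assert ibmd_two_observer(pairs) == ibmd(
        RatingsTable.from_rows([list(p) for p in pairs])
    ).ibmd


def test_duplicate_observer_labels_rejected():
    from ibmd import CaseRecord

    with pytest.raises(DataError, match="duplicate observer"):
        CaseRecord("1", np.array([1.0, 2.0]), observers=("j1", "j1"))


def test_all_zero_case_counts_its_pairs():
    # a case of all zeros contributes C(M,2) zero-valued pairs to the mean
    table = RatingsTable.from_rows([[0.0, 0.0, 0.0], [1.0, 2.0]])
    est = ibmd(table)
    assert est.n_pairs_total == 4
    assert est.ibmd == pytest.approx(math.log2(1.5) / 4)
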