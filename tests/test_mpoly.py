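"""BiPoly algebra, the operator calculus, and operator-route indices."""
from fractions import Fraction as F

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpolyindex import (
    BiPoly,
    EdgePartition,
    UndefinedOperatorError,
    edge_partition,
    index_from_operators,
    mpolynomial,
)
from mpolyindex.indices import UndefinedIndexError, direct_index
from mpolyindex.mpoly import apply_chain, apply_operator


def bp(terms):
    return BiPoly(terms)


def test_mpolynomial_guar_gum_n1():
    # x y^2 + 8 x y^3 + 2 x^2 y^2 + 13 x^2 y^3 + 9 x^3 y^3
    part = EdgePartition({(1, 2): 1, (1, 3): 8, (2, 2): 2, (2, 3): 13, (3, 3): 9})
    assert mpolynomial(part) == bp(
        {(1, 2): 1, (1, 3): 8, (2, 2): 2, (2, 3): 13, (3, 3): 9}
    )


def test_mpolynomial_normalization():
    part = EdgePartition({(1, 2): 2})
    assert mpolynomial(part) == bp({(1, 2): 2})
    assert mpolynomial(part).evaluate() == part.total_edges()


def test_monomial_operator_actions():
    m = bp({(1, 2): 1})  # x y^2
    assert apply_operator(m, "Dx") == m
    assert apply_operator(m, "Dy") == bp({(1, 2): 2})
    assert apply_operator(m, "Sy") == bp({(1, 2): F(1, 2)})
    assert apply_operator(m, "Q", -2) == bp({(-1, 2): 1})
    assert apply_operator(m, "J") == bp({(3, 0): 1})


def test_exponent_bookkeeping_through_azi_style_chain():
    # on x^3: Q(-2) gives x^1, Sx leaves x^1 with coefficient unchanged
    cubed = bp({(3, 0): 1})
    shifted = apply_operator(cubed, "Q", -2)
    assert shifted == bp({(1, 0): 1})
    assert apply_operator(shifted, "Sx") == bp({(1, 0): 1})


def test_sx_undefined_on_zero_exponent():
    with pytest.raises(UndefinedOperatorError):
        apply_operator(bp({(0, 1): 1}), "Sx")


def test_fractional_power_of_negative_exponent_rejected():
    with pytest.raises(UndefinedOperatorError):
        apply_operator(bp({(-1, 1): 1}), "Dx^a", F(1, 2))


def test_chain_is_right_to_left():
    # J then Q(-2): x y^2 -> x^3 -> x^1
    out = apply_chain(bp({(1, 2): 1}), [("Q", -2), ("J", None)])
    assert out == bp({(1, 0): 1})
    with pytest.raises(ValueError):
        apply_chain(bp({(1, 2): 1}), [])


exponents = st.integers(min_value=1, max_value=6)
coeffs = st.fractions(
    min_value=-10, max_value=10, max_denominator=20
).filter(lambda c: c != 0)
polys = st.dictionaries(
    st.tuples(exponents, exponents), coeffs, min_size=1, max_size=6
).map(BiPoly)


@settings(max_examples=60, derandomize=True)
@given(polys)
def test_dx_sx_inverse(p):
    """Dx and Sx invert each other on positive x-exponents."""
    assert p.s_x().d_x() == p
    assert p.d_x().s_x() == p


@settings(max_examples=60, derandomize=True)
@given(polys, st.fractions(min_value=-3, max_value=3, max_denominator=4),
       st.fractions(min_value=-3, max_value=3, max_denominator=4))
def test_shift_composition_and_diagonal_scaling(p, a, b):
    """Q(a)Q(b) = Q(a+b); J commutes with coefficient scaling."""
    assert p.shift_x(a).shift_x(b) == p.shift_x(a + b)
    assert p.scale(F(3, 7)).diagonal() == p.diagonal().scale(F(3, 7))


def test_bipoly_json_roundtrip():
    p = bp({(F(1, 2), 3): F(-7, 3), (2, 2): 5})
    assert BiPoly.from_json(p.to_json()) == p


def test_operator_route_arabinose_azi():
    part = EdgePartition({(1, 3): 4, (2, 2): 1, (2, 3): 2, (3, 3): 3})
    assert index_from_operators(part, "AZI") == F(4587, 64)  # 71.671875


def test_operator_route_path_m1():
    assert index_from_operators(EdgePartition({(1, 2): 2}), "M1") == 6


def test_azi_undefined_on_1_1_edge():
    part = EdgePartition({(1, 1): 1, (1, 2): 2})
    with pytest.raises(UndefinedOperatorError):
        index_from_operators(part, "AZI")


def test_m1_row_closed_form_on_random_partitions():
    """(Dx + Dy) at (1,1) equals sum m_st (s+t) on 200 seeded partitions."""
    import random

    rng = random.Random(42)
    for _ in range(200):
        counts = {
            (s, t): rng.randint(1, 9)
            for s in range(1, 5)
            for t in range(s, 5)
            if rng.random() < 0.5
        } or {(1, 2): 1}
        part = EdgePartition(counts)
        g = mpolynomial(part)
        assert (g.d_x() + g.d_y()).evaluate() == sum(
            c * (s + t) for (s, t), c in part.items()
        )
        assert g.evaluate() == part.total_edges()


@pytest.mark.parametrize("name", ["M1", "M2", "mM2", "SDD", "H", "I", "AZI"])
def test_operator_equals_direct_on_random_graphs(name, random_graphs):
    for g in random_graphs(50, n_vertices=12, seed0=500):
        part = edge_partition(g)
        try:
            expected = direct_index(part, name)
        except UndefinedIndexError:
            with pytest.raises(UndefinedOperatorError):
                index_from_operators(part, name)
            continue
        assert index_from_operators(part, name) == expected


@pytest.mark.parametrize("alpha", [F(1, 2), F(-1, 2), 1, -1, 2])
@pytest.mark.parametrize("name", ["R", "RR"])
def test_operator_equals_direct_randic(name, alpha, random_graphs):
    for g in random_graphs(10, n_vertices=12, seed0=900):
        part = edge_partition(g)
        a = float(direct_index(part, name, alpha))
        b = float(index_from_operators(part, name, alpha))
        assert abs(a - b) < 1e-9
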