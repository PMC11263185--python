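"""Sparse bivariate polynomials and the M-polynomial operator calculus.

The M-polynomial of a graph G is ``M(G; x, y) = sum_{s<=t} m_st x^s y^t``
where ``m_st`` counts edges whose endpoint degrees are ``{s, t}``.  Every
degree-based index handled here is obtained by applying a short chain of
per-term operators to M and evaluating at ``x = y = 1``:

========  =====================================
index     operator chain (applied right-to-left)
========  =====================================
M1        (Dx + Dy)
M2        Dx Dy
mM2       Sx Sy
R_a       Dx^a Dy^a
RR_a      Sx^a Sy^a
SDD       Dx Sy + Sx Dy
H         2 Sx J
I         Sx J Dx Dy
AZI       Sx^3 Q(-2) J Dx^3 Dy^3
========  =====================================

with the per-term actions on ``c x^i y^j``:

* ``Dx``: multiply the coefficient by ``i`` (``x d/dx``); ``Dy`` likewise by ``j``;
* ``Sx``: divide by ``i`` (the operator ``int_0^x g(t,y)/t dt``), undefined
  when a term has ``i == 0``; ``Sy`` likewise;
* ``Dx^a`` / ``Sx^a``: multiply / divide by ``i^a`` for rational ``a``;
* ``Q(a)``: shift the x-exponent by ``a`` (may go negative transiently);
* ``J``: diagonal substitution ``y -> x``, collapsing to ``c x^(i+j)``.

Coefficients and exponents are exact rationals throughout; floats appear
only when a genuinely irrational power (fractional ``a``) is requested, or
at final evaluation.  The AZI chain makes the one deliberate failure mode
visible: on a (1,1) edge the divisor ``(d_u + d_v - 2)^3`` is zero, which
surfaces as ``Sx`` acting on a zero x-exponent after ``Q(-2)``.
"""
from __future__ import annotations

import json
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Union

from .graphs import EdgePartition

__all__ = [
    "BiPoly",
    "UndefinedOperatorError",
    "apply_operator",
    "apply_chain",
    "INDEX_CHAINS",
    "mpolynomial",
    "index_from_operators",
]

Coeff = Union[Fraction, float]
Exp = Fraction


class UndefinedOperatorError(ArithmeticError):
    """An operator was applied outside its domain (e.g. Sx on x-exponent 0)."""


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**12)
    return Fraction(value)


def _pow(base: Fraction, alpha: Fraction) -> Coeff:
    """``base ** alpha`` exactly for integer alpha, as float otherwise."""
    if alpha.denominator == 1:
        if base == 0 and alpha < 0:
            raise UndefinedOperatorError("0 raised to a negative power")
        return base ** int(alpha)
    if base < 0:
        raise UndefinedOperatorError(
            f"fractional power {alpha} of negative base {base}"
        )
    return float(base) ** float(alpha)


class BiPoly:
    """Sparse bivariate polynomial with rational coefficients and exponents.

    ``terms`` maps exponent pairs ``(i, j)`` to coefficients.  Exponents are
    normally positive integers (degree pairs) but become negative or
    fractional under the shift and power operators.  Zero-coefficient terms
    are never stored.
    """

    def __init__(self, terms: Mapping[tuple, Coeff] | Iterable[tuple]):
        items = terms.items() if isinstance(terms, Mapping) else terms
        acc: dict[tuple[Exp, Exp], Coeff] = {}
        for (i, j), c in items:
            key = (_as_fraction(i), _as_fraction(j))
            if not isinstance(c, float):
                c = _as_fraction(c)
            acc[key] = acc.get(key, 0) + c
        self.terms: dict[tuple[Exp, Exp], Coeff] = {
            k: v for k, v in sorted(acc.items()) if v != 0
        }

    # -- algebra (only what the operator calculus needs) --------------------

    def __add__(self, other: "BiPoly") -> "BiPoly":
        merged = dict(self.terms)
        for k, v in other.terms.items():
            merged[k] = merged.get(k, 0) + v
        return BiPoly(merged)

    def scale(self, factor) -> "BiPoly":
        factor = factor if isinstance(factor, float) else _as_fraction(factor)
        return BiPoly({k: factor * v for k, v in self.terms.items()})

    def __eq__(self, other) -> bool:
        return isinstance(other, BiPoly) and self.terms == other.terms

    def __repr__(self) -> str:
        body = " + ".join(f"{c}*x^{i}*y^{j}" for (i, j), c in self.terms.items())
        return f"BiPoly({body or '0'})"

    def evaluate(self, x=1, y=1):
        """Evaluate; with the defaults this is just the coefficient sum."""
        if x == 1 and y == 1:
            return sum(self.terms.values())
        total = 0
        for (i, j), c in self.terms.items():
            total += c * _pow(_as_fraction(x), i) * _pow(_as_fraction(y), j)
        return total

    # -- per-term operators --------------------------------------------------

    def d_x(self, alpha=1) -> "BiPoly":
        a = _as_fraction(alpha)
        return BiPoly({(i, j): c * _pow(i, a) for (i, j), c in self.terms.items()})

    def d_y(self, alpha=1) -> "BiPoly":
        a = _as_fraction(alpha)
        return BiPoly({(i, j): c * _pow(j, a) for (i, j), c in self.terms.items()})

    def s_x(self, alpha=1) -> "BiPoly":
        a = _as_fraction(alpha)
        out = {}
        for (i, j), c in self.terms.items():
            if i == 0:
                raise UndefinedOperatorError(
                    f"Sx undefined on term {c}*x^{i}*y^{j} (zero x-exponent)"
                )
            out[(i, j)] = c * _pow(i, -a)
        return BiPoly(out)

    def s_y(self, alpha=1) -> "BiPoly":
        a = _as_fraction(alpha)
        out = {}
        for (i, j), c in self.terms.items():
            if j == 0:
                raise UndefinedOperatorError(
                    f"Sy undefined on term {c}*x^{i}*y^{j} (zero y-exponent)"
                )
            out[(i, j)] = c * _pow(j, -a)
        return BiPoly(out)

    def shift_x(self, alpha) -> "BiPoly":
        """The exponent-shift operator Q(alpha): x^i -> x^(i+alpha)."""
        a = _as_fraction(alpha)
        return BiPoly({(i + a, j): c for (i, j), c in self.terms.items()})

    def diagonal(self) -> "BiPoly":
        """Diagonal substitution J: g(x, y) -> g(x, x), kept as x^(i+j) y^0."""
        out: dict[tuple, Coeff] = {}
        for (i, j), c in self.terms.items():
            key = (i + j, Fraction(0))
            out[key] = out.get(key, 0) + c
        return BiPoly(out)

    # -- JSON round-trip -----------------------------------------------------

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, float):
                return v
            f = _as_fraction(v)
            return f"{f.numerator}/{f.denominator}"

        return json.dumps(
            [
                {"i": enc(i), "j": enc(j), "coeff": enc(c)}
                for (i, j), c in self.terms.items()
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "BiPoly":
        def dec(v):
            return Fraction(v) if isinstance(v, str) else v

        return cls(
            {(dec(t["i"]), dec(t["j"])): dec(t["coeff"]) for t in json.loads(text)}
        )


def mpolynomial(partition: EdgePartition) -> BiPoly:
    """M-polynomial of an edge partition: term (s, t) with coefficient m_st."""
    return BiPoly({(s, t): c for (s, t), c in partition.items()})


def apply_operator(poly: BiPoly, tag: str, alpha=None) -> BiPoly:
    """Apply a single named operator; ``alpha`` only where the tag takes one."""
    if tag == "Dx":
        return poly.d_x()
    if tag == "Dy":
        return poly.d_y()
    if tag == "Sx":
        return poly.s_x()
    if tag == "Sy":
        return poly.s_y()
    if tag == "J":
        return poly.diagonal()
    if tag == "Q":
        return poly.shift_x(alpha)
    if tag == "Dx^a":
        return poly.d_x(alpha)
    if tag == "Dy^a":
        return poly.d_y(alpha)
    if tag == "Sx^a":
        return poly.s_x(alpha)
    if tag == "Sy^a":
        return poly.s_y(alpha)
    raise ValueError(f"unknown operator tag {tag!r}")


def apply_chain(poly: BiPoly, chain: list[tuple[str, object]]) -> BiPoly:
    """Apply a chain written left-to-right as composition, i.e. the last
    element of *chain* acts first (right-to-left application)."""
    if not chain:
        raise ValueError("operator chain must be non-empty")
    for tag, alpha in reversed(chain):
        poly = apply_operator(poly, tag, alpha)
    return poly


# operator chains, written as composed left-to-right (rightmost acts first)
INDEX_CHAINS: dict[str, list[tuple[str, object]]] = {
    "M2": [("Dx", None), ("Dy", None)],
    "mM2": [("Sx", None), ("Sy", None)],
    "H": [("Sx", None), ("J", None)],
    "I": [("Sx", None), ("J", None), ("Dx", None), ("Dy", None)],
    "AZI": [
        ("Sx^a", 3),
        ("Q", -2),
        ("J", None),
        ("Dx^a", 3),
        ("Dy^a", 3),
    ],
}


def index_from_operators(partition: EdgePartition, name: str, alpha=None):
    """Compute an index from the M-polynomial via its operator chain.

    Returns an exact :class:`fractions.Fraction` whenever the chain stays
    rational (everything except fractional-alpha Randic variants).
    """
    g = mpolynomial(partition)
    if name == "M1":
        return (g.d_x() + g.d_y()).evaluate()
    if name == "SDD":
        return (g.d_x().s_y() + g.s_x().d_y()).evaluate()
    if name == "R":
        if alpha is None:
            raise ValueError("R requires alpha")
        return g.d_x(alpha).d_y(alpha).evaluate()
    if name == "RR":
        if alpha is None:
            raise ValueError("RR requires alpha")
        return g.s_x(alpha).s_y(alpha).evaluate()
    if name == "H":
        return apply_chain(g, INDEX_CHAINS["H"]).scale(2).evaluate()
    if name in INDEX_CHAINS:
        return apply_chain(g, INDEX_CHAINS[name]).evaluate()
    raise ValueError(f"unknown index {name!r}")
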