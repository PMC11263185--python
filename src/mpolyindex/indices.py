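"""Direct edge-sum topological indices and symbolic linear closed forms.

Every index is a sum over the degree-pair edge partition of
``count(s, t) * kernel(s, t)``:

* ``M1``: s + t (first Zagreb)
* ``M2``: s * t (second Zagreb)
* ``mM2``: 1 / (s * t) (second modified Zagreb)
* ``R`` (alpha): (s * t)^alpha (general Randic; alpha = -1/2 is the classic
  Randic index)
* ``RR`` (alpha): (s * t)^(-alpha) (inverse Randic)
* ``SDD``: s/t + t/s (symmetric division degree)
* ``H``: 2 / (s + t) (harmonic)
* ``I``: s*t / (s + t) (inverse sum indeg)
* ``AZI``: (s*t / (s + t - 2))^3 (augmented Zagreb; undefined on (1,1) edges)

For a parametric partition whose counts are linear in the repeat count n,
each index is itself linear in n; :func:`closed_form` returns that line with
exact rational slope and intercept.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import TYPE_CHECKING, Mapping

import pandas as pd

from .graphs import EdgePartition
from .mpoly import UndefinedOperatorError, _as_fraction, _pow

if TYPE_CHECKING:  # pragma: no cover
    from .families import ParametricPartition

__all__ = [
    "INDEX_NAMES",
    "TABLE_INDEX_NAMES",
    "UndefinedIndexError",
    "IndexValue",
    "LinearForm",
    "edge_kernel",
    "direct_index",
    "index_table",
    "closed_form",
    "round_half_up",
]

#: all supported index identifiers
INDEX_NAMES = ("M1", "M2", "mM2", "R", "RR", "SDD", "H", "I", "AZI")

#: the seven-index column set used in tabulated reports (no alpha needed)
TABLE_INDEX_NAMES = ("H", "I", "AZI", "M1", "M2", "mM2", "SDD")


class UndefinedIndexError(ArithmeticError):
    """The index is undefined on this partition (AZI with (1,1) edges)."""


@dataclass(frozen=True)
class IndexValue:
    name: str
    value: float
    alpha: Fraction | None = None


@dataclass(frozen=True)
class LinearForm:
    """Exact line ``slope * n + intercept`` with rational coefficients."""

    slope: Fraction
    intercept: Fraction

    def __call__(self, n: int) -> Fraction:
        return self.slope * n + self.intercept

    def __repr__(self) -> str:
        return f"LinearForm({self.slope}*n + {self.intercept})"


def edge_kernel(name: str, s: int, t: int, alpha=None):
    """Per-edge contribution of one degree pair to the named index.

    Exact rational except for fractional-alpha Randic variants.
    """
    s, t = (s, t) if s <= t else (t, s)
    if name == "M1":
        return Fraction(s + t)
    if name == "M2":
        return Fraction(s * t)
    if name == "mM2":
        return Fraction(1, s * t)
    if name == "R":
        if alpha is None:
            raise ValueError("R requires alpha")
        return _pow(Fraction(s * t), _as_fraction(alpha))
    if name == "RR":
        if alpha is None:
            raise ValueError("RR requires alpha")
        return _pow(Fraction(s * t), -_as_fraction(alpha))
    if name == "SDD":
        return Fraction(s, t) + Fraction(t, s)
    if name == "H":
        return Fraction(2, s + t)
    if name == "I":
        return Fraction(s * t, s + t)
    if name == "AZI":
        if s + t == 2:
            raise UndefinedIndexError(
                "AZI is undefined on a (1,1) edge: divisor (d_u + d_v - 2) is zero"
            )
        return Fraction(s * t, s + t - 2) ** 3
    raise ValueError(f"unknown index {name!r}")


def direct_index(partition: EdgePartition, name: str, alpha=None):
    """Index value as the direct edge sum over the partition.

    Returns an exact :class:`~fractions.Fraction` for rational kernels.
    """
    total = 0
    for (s, t), count in partition.items():
        total += count * edge_kernel(name, s, t, alpha)
    return total


def round_half_up(value, ndigits: int = 4) -> float:
    """Round with ties away from zero (presentation convention, 4 decimals)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def index_table(
    partitions: Mapping[str, EdgePartition],
    names: tuple[str, ...] = TABLE_INDEX_NAMES,
    alpha=None,
    decimals: int | None = 4,
) -> pd.DataFrame:
    """One row per structure, one column per index.

    Cells where the index is undefined (AZI with a (1,1) edge) hold NaN
    rather than aborting the table.  ``decimals=None`` keeps full precision.
    """
    rows = {}
    for struct, part in partitions.items():
        row = {}
        for name in names:
            try:
                v = direct_index(part, name, alpha)
            except UndefinedIndexError:
                row[name] = float("nan")
                continue
            row[name] = round_half_up(v, decimals) if decimals is not None else float(v)
        rows[struct] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    df.index.name = "structure"
    return df


def closed_form(param: "ParametricPartition", name: str, alpha=None) -> LinearForm:
    """Exact linear-in-n closed form of an index over a parametric family.

    Requires a rational kernel (any index, or R/RR with integer alpha); for
    fractional alpha the per-pair kernel is irrational and no exact line
    exists.
    """
    slope = Fraction(0)
    intercept = Fraction(0)
    for (s, t), form in param.counts.items():
        k = edge_kernel(name, s, t, alpha)
        if not isinstance(k, Fraction):
            raise ValueError(
                f"closed_form needs a rational kernel; {name} with alpha={alpha} is not"
            )
        slope += k * form.slope
        intercept += k * form.intercept
    return LinearForm(slope, intercept)
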