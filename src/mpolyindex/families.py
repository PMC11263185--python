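"""Parametric edge partitions of guar gum and its chemical derivatives.

Guar gum is a galactomannan polysaccharide; hydroxypropyl guar (HPG),
carboxymethyl guar (CMG) and carboxymethyl hydroxypropyl guar (CMHPG) are
its common industrial derivatives.  Modelled as hydrogen-suppressed repeat
chains with repeat count ``n >= 1``, each family's degree-pair edge counts
are exact linear functions of n:

=========  ======  =======  ======  =======  ======
family     (1,2)   (1,3)    (2,2)   (2,3)    (3,3)
=========  ======  =======  ======  =======  ======
guar gum   1       7n + 1   2n      14n - 1  9n
HPG / CMG  2n + 1  7n + 1   4n      14n - 1  12n
CMHPG      3n + 1  6n + 1   5n      15n - 1  12n
=========  ======  =======  ======  =======  ======

HPG and CMG share one edge partition (their substituents differ chemically
but not in heavy-atom degree structure), so they are modelled as a single
parametric object with two display names.  The families are defined by
these count formulas directly; no atom-level repeat-unit graph is
reconstructed.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .graphs import EdgePartition
from .indices import LinearForm, TABLE_INDEX_NAMES, direct_index, round_half_up

__all__ = [
    "ParametricPartition",
    "FAMILY_NAMES",
    "family_partition",
    "instantiate",
    "family_table",
]


@dataclass(frozen=True)
class ParametricPartition:
    """Degree-pair edge counts as linear forms in the repeat count n >= 1."""

    name: str
    counts: dict[tuple[int, int], LinearForm]

    def instantiate(self, n: int) -> EdgePartition:
        return instantiate(self, n)


def _lf(slope: int, intercept: int = 0) -> LinearForm:
    return LinearForm(Fraction(slope), Fraction(intercept))


_GUAR = {
    (1, 2): _lf(0, 1),
    (1, 3): _lf(7, 1),
    (2, 2): _lf(2),
    (2, 3): _lf(14, -1),
    (3, 3): _lf(9),
}
_HPG_CMG = {
    (1, 2): _lf(2, 1),
    (1, 3): _lf(7, 1),
    (2, 2): _lf(4),
    (2, 3): _lf(14, -1),
    (3, 3): _lf(12),
}
_CMHPG = {
    (1, 2): _lf(3, 1),
    (1, 3): _lf(6, 1),
    (2, 2): _lf(5),
    (2, 3): _lf(15, -1),
    (3, 3): _lf(12),
}

_FAMILIES: dict[str, dict] = {
    "guar_gum": _GUAR,
    "hpg": _HPG_CMG,
    "cmg": _HPG_CMG,
    "cmhpg": _CMHPG,
}

FAMILY_NAMES = tuple(_FAMILIES)


def family_partition(name: str) -> ParametricPartition:
    """Parametric partition of a named family (hpg and cmg are aliases)."""
    key = name.lower().replace("-", "_").replace(" ", "_")
    if key not in _FAMILIES:
        raise ValueError(
            f"unknown family {name!r}; valid names: {', '.join(FAMILY_NAMES)}"
        )
    return ParametricPartition(key, dict(_FAMILIES[key]))


def instantiate(param: ParametricPartition, n: int) -> EdgePartition:
    """Evaluate every count at integer ``n >= 1``."""
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"repeat count n must be an integer >= 1, got {n!r}")
    counts = {}
    for pair, form in param.counts.items():
        c = form(n)
        if c.denominator != 1 or c < 0:
            raise ValueError(f"count {c} for pair {pair} at n={n} is not admissible")
        counts[pair] = int(c)
    return EdgePartition(counts)


def family_table(
    name: str,
    n_values,
    index_names: tuple[str, ...] = TABLE_INDEX_NAMES,
    alpha=None,
    decimals: int | None = 4,
) -> pd.DataFrame:
    """Per-n index values for a family (exactly linear in n by construction)."""
    param = family_partition(name)
    rows = []
    for n in n_values:
        part = instantiate(param, n)
        row = {"n": n}
        for idx in index_names:
            v = direct_index(part, idx, alpha)
            row[idx] = round_half_up(v, decimals) if decimals is not None else float(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("n")
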