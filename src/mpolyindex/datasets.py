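"""Packaged carbohydrate fixtures: edge partitions, physicochemical
properties, and the as-published index table.

Eight small carbohydrates (arabinose, galactose, maltose, sucrose, sorbose,
ribose, hydroxymethyl furfural, raffinose) ship with the package as plain
CSV files, in the same formats the command-line tools accept for user data.
``load_published_indices`` returns the index table exactly as originally
published; :func:`audit_published_indices` compares it cell-by-cell against
values recomputed from the partitions, because several published cells are
internally inconsistent with their own partitions (see ``docs/methods.md``).

The raffinose density is preserved as printed (884.8 g/cm^3) even though it
is physically implausible by three orders of magnitude; downstream density
regressions exclude it by default via an explicit flag rather than silently
correcting the record.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .graphs import EdgePartition
from .indices import TABLE_INDEX_NAMES, index_table

__all__ = [
    "STRUCTURES",
    "canonical_name",
    "load_partitions",
    "load_properties",
    "load_published_indices",
    "recomputed_indices",
    "audit_published_indices",
    "ANOMALOUS_DENSITY_STRUCTURES",
]

#: canonical structure names, in published row order
STRUCTURES = (
    "arabinose",
    "galactose",
    "maltose",
    "sucrose",
    "sorbose",
    "ribose",
    "hmf",
    "raffinose",
)

#: structures whose printed density is physically implausible
ANOMALOUS_DENSITY_STRUCTURES = ("raffinose",)

# hydroxymethyl furfural appears under both abbreviations in the literature
_ALIASES = {"hmp": "hmf"}


def canonical_name(name: str) -> str:
    key = name.lower()
    key = _ALIASES.get(key, key)
    if key not in STRUCTURES:
        raise KeyError(f"unknown structure {name!r}; valid: {', '.join(STRUCTURES)}")
    return key


def _data_path(*parts: str):
    return resources.files("mpolyindex").joinpath("data", *parts)


def load_partitions() -> dict[str, EdgePartition]:
    """The eight degree-pair edge partitions, keyed by canonical name."""
    out = {}
    for name in STRUCTURES:
        with resources.as_file(_data_path("partitions", f"{name}.csv")) as p:
            out[name] = EdgePartition.read_csv(p)
    return out


def load_properties() -> pd.DataFrame:
    """Physicochemical properties, one row per structure.

    Columns: density (g/cm^3), bp (degC), mp (degC), mw (g/mol), ws (g/L).
    """
    with resources.as_file(_data_path("properties.csv")) as p:
        df = pd.read_csv(p, index_col="structure")
    return df


def load_published_indices() -> pd.DataFrame:
    """The seven-index table exactly as originally published (verbatim)."""
    with resources.as_file(_data_path("published_indices.csv")) as p:
        df = pd.read_csv(p, index_col="structure")
    return df


def recomputed_indices(decimals: int | None = 4) -> pd.DataFrame:
    """Index table recomputed from the packaged partitions (canonical output)."""
    return index_table(load_partitions(), TABLE_INDEX_NAMES, decimals=decimals)


def audit_published_indices() -> pd.DataFrame:
    """Cell-by-cell comparison of published vs recomputed index values.

    Returns the rows (structure, index, published, recomputed) where the two
    disagree after half-up rounding to four decimals.
    """
    published = load_published_indices()
    recomputed = recomputed_indices(decimals=4)
    rows = []
    for struct in STRUCTURES:
        for idx in TABLE_INDEX_NAMES:
            pub = float(published.loc[struct, idx])
            rec = float(recomputed.loc[struct, idx])
            if abs(pub - rec) > 1e-12:
                rows.append(
                    {"structure": struct, "index": idx, "published": pub,
                     "recomputed": rec}
                )
    return pd.DataFrame(rows, columns=["structure", "index", "published", "recomputed"])
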