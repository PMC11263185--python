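"""Hydrogen-suppressed molecular graphs and degree-pair edge partitions.

A molecular graph here is the heavy-atom skeleton of a molecule: hydrogens
are omitted and every vertex degree counts heavy-atom neighbours only.  All
degree-based topological indices consume nothing but the *edge partition* of
such a graph -- the multiset of edges grouped by the unordered degree pair
of their endpoints -- so the partition is the universal intermediate object
of this package.
"""
from __future__ import annotations

import random
import warnings
from collections import Counter
from collections.abc import Hashable, Iterable, Mapping
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "GraphInputError",
    "MolecularGraph",
    "EdgePartition",
    "degrees",
    "edge_partition",
    "read_edge_list",
    "random_chemical_graph",
    "from_smiles",
    "from_molfile",
]


class GraphInputError(ValueError):
    """Raised for malformed graph input (self-loops, isolated vertices, ...)."""


class MolecularGraph:
    """Simple undirected graph of heavy atoms.

    Parameters
    ----------
    edges
        Iterable of vertex-identifier pairs.  Identifiers are opaque and
        hashable; element labels carry no semantics for any index.
        Duplicate edges collapse (bond order is irrelevant to degree-based
        indices); self-loops are rejected.
    labels
        Optional map from identifier to element symbol, informational only.
    """

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable]],
        labels: Mapping[Hashable, str] | None = None,
    ):
        edge_set: set[frozenset] = set()
        for u, v in edges:
            if u == v:
                raise GraphInputError(f"self-loop on vertex {u!r} is not allowed")
            edge_set.add(frozenset((u, v)))
        if not edge_set:
            raise GraphInputError("a molecular graph needs at least one edge")
        self._edges = frozenset(edge_set)
        self._vertices = frozenset(v for e in self._edges for v in e)
        self.labels = dict(labels) if labels else {}
        # all vertices come from edges, so no isolated vertex can exist;
        # connectivity is only advisory (indices are edge-local)
        if not nx.is_connected(self.to_networkx()):
            warnings.warn(
                "molecular graph is disconnected; indices remain well-defined",
                stacklevel=2,
            )

    @property
    def vertices(self) -> frozenset:
        return self._vertices

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._vertices)
        g.add_edges_from(tuple(e) for e in self._edges)
        return g

    def __eq__(self, other) -> bool:
        return isinstance(other, MolecularGraph) and self._edges == other._edges

    def __hash__(self) -> int:
        return hash(self._edges)

    def __repr__(self) -> str:
        return f"MolecularGraph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


class EdgePartition:
    """Map from ordered degree pair ``(s, t)``, ``s <= t``, to an edge count.

    This is the sole input of every topological index: the M-polynomial is
    ``sum_{s<=t} m_st x^s y^t`` where ``m_st`` is ``counts[(s, t)]``.
    """

    def __init__(self, counts: Mapping[tuple[int, int], int]):
        norm: dict[tuple[int, int], int] = {}
        for (s, t), c in counts.items():
            s, t = int(s), int(t)
            if s > t:
                s, t = t, s
            if s < 1:
                raise ValueError(f"degree pair ({s},{t}) has degree < 1")
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count {c} for pair ({s},{t})")
            if c:
                norm[(s, t)] = norm.get((s, t), 0) + c
        self.counts: dict[tuple[int, int], int] = dict(sorted(norm.items()))

    def total_edges(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return self.counts.items()

    def __getitem__(self, pair: tuple[int, int]) -> int:
        s, t = pair
        if s > t:
            s, t = t, s
        return self.counts.get((s, t), 0)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgePartition) and self.counts == other.counts

    def __repr__(self) -> str:
        return f"EdgePartition({self.counts})"

    @classmethod
    def from_graph(cls, graph: MolecularGraph) -> "EdgePartition":
        return edge_partition(graph)

    # -- CSV round-trip: header `s,t,count`, integers, bit-exact ------------

    def to_csv(self, path: str | Path) -> None:
        rows = [{"s": s, "t": t, "count": c} for (s, t), c in self.counts.items()]
        pd.DataFrame(rows, columns=["s", "t", "count"]).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "EdgePartition":
        df = pd.read_csv(path, dtype=int)
        missing = {"s", "t", "count"} - set(df.columns)
        if missing:
            raise GraphInputError(
                f"partition CSV {path} lacks column(s): {sorted(missing)}"
            )
        return cls({(row.s, row.t): row.count for row in df.itertuples()})


def degrees(graph: MolecularGraph) -> dict:
    """Degree of every vertex (number of heavy-atom neighbours)."""
    deg: Counter = Counter()
    for e in graph.edges:
        for v in e:
            deg[v] += 1
    return dict(deg)


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Group the edges of *graph* by the unordered degree pair of endpoints."""
    deg = degrees(graph)
    counts: Counter = Counter()
    for e in graph.edges:
        u, v = tuple(e)
        s, t = sorted((deg[u], deg[v]))
        counts[(s, t)] += 1
    return EdgePartition(counts)


def read_edge_list(path: str | Path) -> MolecularGraph:
    """Read a graph from a plain edge-list file.

    One edge per line, two whitespace-separated vertex tokens; ``#`` starts
    a comment.  Duplicate lines collapse to one edge; a self-loop line is a
    :class:`GraphInputError` naming the offending line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphInputError(
                    f"{path}:{lineno}: expected two vertex tokens, got {len(tokens)}"
                )
            u, v = tokens
            if u == v:
                raise GraphInputError(f"{path}:{lineno}: self-loop on {u!r}")
            edges.append((u, v))
    if not edges:
        raise GraphInputError(f"{path}: no edges found")
    return MolecularGraph(edges)


def random_chemical_graph(
    n_vertices: int, max_degree: int = 4, seed: int = 0
) -> MolecularGraph:
    """Seeded random connected graph with all degrees in ``[1, max_degree]``.

    Grows a random tree by attaching each new vertex to a uniformly chosen
    existing vertex with spare valence, then adds a few random ring-closure
    edges, mimicking the degree profile of organic skeletons.  Identical
    seeds give identical edge sets.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if not 2 <= max_degree <= 4:
        raise ValueError("max_degree must be in [2, 4]")
    rng = random.Random(seed)
    deg = {0: 1, 1: 1}
    edges = [(0, 1)]
    for new in range(2, n_vertices):
        candidates = [v for v, d in deg.items() if d < max_degree]
        if not candidates:  # cannot happen for max_degree >= 2, kept as a guard
            raise ValueError("degree constraint infeasible")
        host = rng.choice(candidates)
        edges.append((host, new))
        deg[host] += 1
        deg[new] = 1
    # ring closures: bounded attempts between non-adjacent spare-valence pairs
    existing = {frozenset(e) for e in edges}
    for _ in range(n_vertices // 4):
        spare = [v for v, d in deg.items() if d < max_degree]
        if len(spare) < 2:
            break
        u, v = rng.sample(spare, 2)
        if frozenset((u, v)) in existing:
            continue
        edges.append((u, v))
        existing.add(frozenset((u, v)))
        deg[u] += 1
        deg[v] += 1
    return MolecularGraph((f"v{u}", f"v{v}") for u, v in edges)


# -- optional cheminformatics ingestion (rdkit) -----------------------------


def _mol_to_graph(mol) -> MolecularGraph:
    from rdkit import Chem

    mol = Chem.RemoveHs(mol)
    edges = []
    labels = {}
    for atom in mol.GetAtoms():
        labels[atom.GetIdx()] = atom.GetSymbol()
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return MolecularGraph(edges, labels=labels)


def from_smiles(smiles: str) -> MolecularGraph:
    """Hydrogen-suppressed skeleton of a SMILES string (requires rdkit)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphInputError(f"could not parse SMILES {smiles!r}")
    return _mol_to_graph(mol)


def from_molfile(path: str | Path) -> MolecularGraph:
    """Hydrogen-suppressed skeleton of a MOL (V2000) file (requires rdkit)."""
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path))
    if mol is None:
        raise GraphInputError(f"could not parse MOL file {path}")
    return _mol_to_graph(mol)
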