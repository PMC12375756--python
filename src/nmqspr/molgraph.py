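"""Molecular graphs, neighborhood degree-sum weights, and edge partitions.

A molecule enters the pipeline as a hydrogen-suppressed skeleton: heavy atoms
are vertices, covalent bonds are edges, and no element or bond-order
information is kept — every downstream quantity depends on topology alone.
The front of the pipeline assigns each vertex v its neighborhood degree sum

    S(v) = sum of deg(u) over u in the open neighborhood N(v),

and groups the edges uv by the unordered pair {S(u), S(v)}.  The resulting
multiset ``m(i, j)`` (the edge partition) is the sole input to both the
NM-polynomial and the direct index formulas.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "GraphValidationError",
    "EdgeListParseError",
    "MolecularGraph",
    "EdgePartition",
    "neighborhood_weights",
    "edge_partition",
    "read_edge_list",
]


class GraphValidationError(ValueError):
    """Raised when a graph violates the molecular-graph invariants."""


class EdgeListParseError(ValueError):
    """Raised on malformed edge-list input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class MolecularGraph:
    """Simple connected undirected graph with opaque vertex labels.

    Vertices keep first-insertion order (fixture files use 1-based integer
    strings purely for readability).  Self-loops, duplicate edges and
    disconnected inputs are rejected at construction.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            if g.has_edge(u, v):
                raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v)
        if g.number_of_nodes() < 2:
            raise GraphValidationError("molecular graph needs at least 2 vertices")
        if not nx.is_connected(g):
            raise GraphValidationError("molecular graph must be connected")
        self._g = g

    @property
    def nx_graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def relabeled(self, mapping: Mapping[str, str]) -> "MolecularGraph":
        """Return a copy with vertices renamed; used by isomorphism tests."""
        return MolecularGraph((mapping[u], mapping[v]) for u, v in self.edges)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


@dataclass(frozen=True)
class EdgePartition:
    """Multiset {(i, j): count} of neighborhood degree-sum pairs, i <= j.

    ``counts[(i, j)]`` is m(i, j): the number of edges whose endpoint weights
    are {i, j}.  When derived from a graph the counts sum to |E|.
    """

    counts: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        normalized: dict[tuple[int, int], int] = {}
        for (i, j), m in dict(self.counts).items():
            i, j = int(i), int(j)
            if i < 1 or j < 1:
                raise ValueError(f"partition class ({i},{j}) has non-positive weight")
            if int(m) < 1:
                raise ValueError(f"partition class ({i},{j}) has non-positive count {m}")
            key = (i, j) if i <= j else (j, i)
            normalized[key] = normalized.get(key, 0) + int(m)
        object.__setattr__(self, "counts", normalized)

    @property
    def total_edges(self) -> int:
        return sum(self.counts.values())

    def items(self) -> Iterator[tuple[tuple[int, int], int]]:
        return iter(sorted(self.counts.items()))

    def scaled(self, factor: int) -> "EdgePartition":
        return EdgePartition({k: m * factor for k, m in self.counts.items()})

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgePartition) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))


def neighborhood_weights(g: MolecularGraph) -> dict[str, int]:
    """Neighborhood degree sum S(v) = sum of degrees over the open neighborhood.

    For a connected graph on >= 2 vertices every vertex has a neighbor of
    degree >= 1, so all weights are positive.
    """
    nxg = g.nx_graph
    return {v: sum(nxg.degree[u] for u in nxg.neighbors(v)) for v in nxg.nodes}


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Tally each edge uv under the normalized pair (min(S(u),S(v)), max(...))."""
    s = neighborhood_weights(g)
    tally: Counter[tuple[int, int]] = Counter()
    for u, v in g.edges:
        i, j = sorted((s[u], s[v]))
        tally[(i, j)] += 1
    return EdgePartition(tally)


def read_edge_list(stream: IO[str] | str) -> MolecularGraph:
    """Parse a whitespace-separated two-column edge list into a graph.

    One edge per line; blank lines and ``#`` comments are skipped.  Validation
    failures report the offending line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise EdgeListParseError(
                f"expected two columns, got {len(fields)}: {raw!r}", lineno
            )
        u, v = fields
        if u == v:
            raise EdgeListParseError(f"self-loop at vertex {u!r}", lineno)
        key = frozenset((u, v))
        if key in seen:
            raise EdgeListParseError(f"duplicate edge {u!r}-{v!r}", lineno)
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise EdgeListParseError("no edges found in input")
    try:
        return MolecularGraph(edges)
    except GraphValidationError as exc:
        raise EdgeListParseError(str(exc)) from exc


def write_edge_list(g: MolecularGraph, stream: IO[str]) -> None:
    """Write the graph back out as TSV (inverse of :func:`read_edge_list`)."""
    for u, v in g.edges:
        stream.write(f"{u}\t{v}\n")
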