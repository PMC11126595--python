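"""Two-mode (bipartite) network container, edge-list I/O and descriptive statistics.

The central object is :class:`BipartiteNetwork`: two disjoint node sets
(``part_a``, e.g. probiotic strains; ``part_b``, e.g. ICD-coded diseases) and a
set of unordered cross-part edges. Node identifiers are opaque trimmed strings;
no taxonomy or ontology normalisation is attempted. The neighbour algebra that
all similarity scores build on lives here: ``neighbors`` returns the one-hop
set Γ(x) (always in the opposite part) and ``second_neighbors`` the two-hop set
Γ(Γ(x)) (always in x's own part), the latter cached because scoring visits it
repeatedly. Networks are treated as immutable once constructed; derived
networks (edge removal, ego stars) are new objects.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import (
    EmptyPartError,
    ParseError,
    PartConflictError,
    PartError,
    UnknownNodeError,
)

logger = logging.getLogger(__name__)

#: An edge is an (part-A id, part-B id) pair; stored in that canonical orientation.
Edge = tuple[str, str]

PART_A = "a"
PART_B = "b"


def _clean_id(raw: str, *, line: int | None = None) -> str:
    value = raw.strip()
    if not value:
        raise ParseError("empty node identifier", line=line)
    return value


class BipartiteNetwork:
    """An undirected two-mode network with edges only between the two parts.

    Parameters
    ----------
    part_a, part_b
        Iterables of node identifiers (whitespace-trimmed, non-empty, and the
        two parts must be disjoint). Nodes with no incident edge are kept, so
        isolated nodes are representable.
    edges
        Iterable of ``(a, b)`` pairs with ``a`` in part A and ``b`` in part B.
        Duplicates collapse by set semantics.
    """

    __slots__ = ("_adj", "_part_a", "_part_b", "_edges", "_second_cache")

    def __init__(
        self,
        part_a: Iterable[str],
        part_b: Iterable[str],
        edges: Iterable[Edge] = (),
    ):
        pa = frozenset(_clean_id(x) for x in part_a)
        pb = frozenset(_clean_id(x) for x in part_b)
        overlap = pa & pb
        if overlap:
            raise PartConflictError(
                f"identifiers present in both parts: {sorted(overlap)[:5]}"
            )
        adj: dict[str, set[str]] = {x: set() for x in pa | pb}
        edge_set: set[Edge] = set()
        for a, b in edges:
            a, b = a.strip(), b.strip()
            if a not in pa:
                if a in pb:
                    raise PartError(f"edge endpoint {a!r} is in part B, expected part A")
                raise UnknownNodeError(f"edge endpoint {a!r} not in part A")
            if b not in pb:
                if b in pa:
                    raise PartError(f"edge endpoint {b!r} is in part A, expected part B")
                raise UnknownNodeError(f"edge endpoint {b!r} not in part B")
            if (a, b) not in edge_set:
                edge_set.add((a, b))
                adj[a].add(b)
                adj[b].add(a)
        self._part_a = pa
        self._part_b = pb
        self._edges = frozenset(edge_set)
        self._adj = {x: frozenset(nb) for x, nb in adj.items()}
        self._second_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def part_a(self) -> frozenset[str]:
        return self._part_a

    @property
    def part_b(self) -> frozenset[str]:
        return self._part_b

    @property
    def edges(self) -> frozenset[Edge]:
        """Edges as canonical ``(part_a_id, part_b_id)`` pairs."""
        return self._edges

    @property
    def n_a(self) -> int:
        return len(self._part_a)

    @property
    def n_b(self) -> int:
        return len(self._part_b)

    @property
    def m(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def part_of(self, node: str) -> str:
        """Return ``"a"`` or ``"b"`` for a known node."""
        if node in self._part_a:
            return PART_A
        if node in self._part_b:
            return PART_B
        raise UnknownNodeError(f"unknown node {node!r}")

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self._edges

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    # -- neighbour algebra -------------------------------------------------

    def neighbors(self, node: str) -> frozenset[str]:
        """Γ(x): the one-hop neighbour set, a subset of the opposite part."""
        try:
            return self._adj[node]
        except KeyError:
            raise UnknownNodeError(f"unknown node {node!r}") from None

    def second_neighbors(self, node: str) -> frozenset[str]:
        """Γ(Γ(x)): the union of neighbour sets of x's neighbours.

        Lies in x's own part; x itself is retained whenever it is reachable in
        two hops (it always is, unless isolated). Cached per node.
        """
        cached = self._second_cache.get(node)
        if cached is not None:
            return cached
        nbrs = self.neighbors(node)
        second: frozenset[str] = (
            frozenset().union(*(self._adj[z] for z in nbrs)) if nbrs else frozenset()
        )
        self._second_cache[node] = second
        return second

    # -- derived networks --------------------------------------------------

    def without_edges(self, removed: Iterable[Edge]) -> "BipartiteNetwork":
        """A copy with the given edges removed; node sets are untouched."""
        removed = set(removed)
        missing = removed - self._edges
        if missing:
            raise UnknownNodeError(
                f"cannot remove non-existent edges, e.g. {sorted(missing)[0]}"
            )
        return BipartiteNetwork(self._part_a, self._part_b, self._edges - removed)

    def ego_subnetwork(self, node: str) -> "BipartiteNetwork":
        """The induced star of ``node``: the node, Γ(node), and the edges between."""
        nbrs = self.neighbors(node)
        if self.part_of(node) == PART_A:
            return BipartiteNetwork([node], nbrs, [(node, b) for b in nbrs])
        return BipartiteNetwork(nbrs, [node], [(a, node) for a in nbrs])

    def non_edges(self) -> Iterator[Edge]:
        """All cross-part pairs that are not edges, in (a, b) lexicographic order."""
        for a in sorted(self._part_a):
            nbrs = self._adj[a]
            for b in sorted(self._part_b):
                if b not in nbrs:
                    yield (a, b)

    # -- interop -----------------------------------------------------------

    def to_networkx(self):
        """Export to a ``networkx.Graph`` with the conventional ``bipartite`` attribute."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self._part_a), bipartite=0)
        g.add_nodes_from(sorted(self._part_b), bipartite=1)
        g.add_edges_from(sorted(self._edges))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self._part_a == other._part_a
            and self._part_b == other._part_b
            and self._edges == other._edges
        )

    def __hash__(self) -> int:
        return hash((self._part_a, self._part_b, self._edges))

    def __repr__(self) -> str:
        return f"BipartiteNetwork(n_a={self.n_a}, n_b={self.n_b}, m={self.m})"


# -- edge-list I/O ---------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    return ","


def load_edge_list(
    source: str | IO[str],
    delimiter: str | None = None,
    header: bool = False,
) -> BipartiteNetwork:
    """Read a two-column delimited edge list into a :class:`BipartiteNetwork`.

    Column 1 holds part-A identifiers, column 2 part-B identifiers. The
    delimiter is auto-detected (tab vs comma) when not given. Duplicate rows
    collapse to a single edge with the count logged; row order never affects
    the result.

    Raises
    ------
    ParseError
        For a row without exactly two non-empty fields (names the line number).
    PartConflictError
        If some identifier appears in both columns.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return load_edge_list(fh, delimiter=delimiter, header=header)

    text = source.read()
    lines = text.splitlines()
    # skip blank lines and provenance comments
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if header and rows:
        rows = rows[1:]
    if not rows:
        raise ParseError("no data rows in input")
    if delimiter is None:
        delimiter = _sniff_delimiter(rows[0][1])

    part_a: set[str] = set()
    part_b: set[str] = set()
    edges: set[Edge] = set()
    duplicates = 0
    for lineno, line in rows:
        fields = next(csv.reader(io.StringIO(line), delimiter=delimiter))
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 fields, found {len(fields)}", line=lineno
            )
        a = _clean_id(fields[0], line=lineno)
        b = _clean_id(fields[1], line=lineno)
        if (a, b) in edges:
            duplicates += 1
            continue
        part_a.add(a)
        part_b.add(b)
        edges.add((a, b))
    conflict = part_a & part_b
    if conflict:
        raise PartConflictError(
            f"identifiers appear in both columns: {sorted(conflict)[:5]}"
        )
    if duplicates:
        logger.info("collapsed %d duplicate edge rows", duplicates)
    return BipartiteNetwork(part_a, part_b, edges)


def write_edge_list(
    net: BipartiteNetwork,
    target: str | IO[str],
    delimiter: str = ",",
    provenance: str | None = None,
) -> None:
    """Write the network's edges as a two-column delimited file (sorted rows).

    Isolated nodes cannot be represented in a pure edge list and are dropped
    with a logged count.
    """
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8", newline="") as fh:
            write_edge_list(net, fh, delimiter=delimiter, provenance=provenance)
        return
    isolated = sum(1 for x in (net.part_a | net.part_b) if not net.neighbors(x))
    if isolated:
        logger.info("%d isolated nodes not representable in edge list output", isolated)
    if provenance:
        for ln in provenance.splitlines():
            target.write(f"# {ln}\n")
    for a, b in sorted(net.edges):
        target.write(f"{a}{delimiter}{b}\n")


# -- descriptive statistics ------------------------------------------------


@dataclass(frozen=True)
class NetworkStats:
    """Whole-network summary: counts, average degrees, density, per-node degrees.

    ``density`` is m / (n_a * n_b), the fraction of possible cross-part pairs
    that exist; all fields are exact, with display rounding (density to five
    decimals, average degrees to the nearest integer) applied only in
    serialisation.
    """

    n_a: int
    n_b: int
    m: int
    avg_degree_a: float
    avg_degree_b: float
    possible_pairs: int
    density: float
    degree_table: dict[str, dict[str, int]] = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "m": self.m,
            "possible_pairs": self.possible_pairs,
            "density": self.density,
            "density_display": round(self.density, 5),
            "avg_degree_a": self.avg_degree_a,
            "avg_degree_b": self.avg_degree_b,
            "avg_degree_a_display": round(self.avg_degree_a),
            "avg_degree_b_display": round(self.avg_degree_b),
        }

    def to_tsv(self) -> str:
        d = self.to_json_dict()
        lines = ["property\tvalue"]
        lines += [f"{k}\t{v}" for k, v in d.items()]
        return "\n".join(lines) + "\n"


def summarize(net: BipartiteNetwork) -> NetworkStats:
    """Compute the Table-3-style summary of a network.

    Raises :class:`EmptyPartError` when either part is empty (density and the
    corresponding average degree are undefined).
    """
    if net.n_a == 0 or net.n_b == 0:
        raise EmptyPartError("density undefined: a part of the network is empty")
    possible = net.n_a * net.n_b
    return NetworkStats(
        n_a=net.n_a,
        n_b=net.n_b,
        m=net.m,
        avg_degree_a=net.m / net.n_a,
        avg_degree_b=net.m / net.n_b,
        possible_pairs=possible,
        density=net.m / possible,
        degree_table={
            "a": {x: net.degree(x) for x in sorted(net.part_a)},
            "b": {x: net.degree(x) for x in sorted(net.part_b)},
        },
    )


@dataclass(frozen=True)
class DegreeExtremes:
    """Top-k and bottom-k degree rankings per part, ties broken by identifier."""

    k: int
    top_a: list[tuple[str, int]]
    bottom_a: list[tuple[str, int]]
    top_b: list[tuple[str, int]]
    bottom_b: list[tuple[str, int]]

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "top_a": self.top_a,
            "bottom_a": self.bottom_a,
            "top_b": self.top_b,
            "bottom_b": self.bottom_b,
        }

    def to_tsv(self) -> str:
        lines = ["part\tlist\trank\tnode\tdegree"]
        for part, name, rows in (
            ("a", "top", self.top_a),
            ("a", "bottom", self.bottom_a),
            ("b", "top", self.top_b),
            ("b", "bottom", self.bottom_b),
        ):
            for rank, (node, deg) in enumerate(rows, start=1):
                lines.append(f"{part}\t{name}\t{rank}\t{node}\t{deg}")
        return "\n".join(lines) + "\n"


def degree_extremes(net: BipartiteNetwork, k: int = 10) -> DegreeExtremes:
    """Table-4-style highest/lowest degree listings for both parts.

    Top lists are non-increasing in degree, bottom lists non-decreasing; ties
    break lexicographically by node id so output is deterministic. ``k``
    larger than a part returns the whole part.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def ranked(part: frozenset[str], reverse: bool) -> list[tuple[str, int]]:
        if reverse:
            key = lambda x: (-net.degree(x), x)
        else:
            key = lambda x: (net.degree(x), x)
        return [(x, net.degree(x)) for x in sorted(part, key=key)[:k]]

    return DegreeExtremes(
        k=k,
        top_a=ranked(net.part_a, True),
        bottom_a=ranked(net.part_a, False),
        top_b=ranked(net.part_b, True),
        bottom_b=ranked(net.part_b, False),
    )


def stats_report_json(stats: NetworkStats, extremes: DegreeExtremes | None = None) -> str:
    """Serialise stats (and optionally extremes) to a JSON report string."""
    doc: dict = {"stats": stats.to_json_dict(), "degree_table": stats.degree_table}
    if extremes is not None:
        doc["degree_extremes"] = extremes.to_json_dict()
    return json.dumps(doc, indent=2, sort_keys=True)
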