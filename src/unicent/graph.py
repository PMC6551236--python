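"""Signed weighted undirected network data model and edge-list I/O.

The central object is :class:`SignedNetwork`: an undirected graph whose
edge weights lie in [-1, 1] excluding 0.  Positive weights encode
cooperative/correlated association (e.g. microbial co-occurrence,
co-expression), negative weights antagonistic association
(co-exclusion).  A zero weight is indistinguishable from the absence of
an edge in every downstream formula, so zero-weight edges are rejected
outright.

Node identifiers are opaque strings.  All deterministic tie-breaks in
the rest of the package rely on their lexicographic order.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import networkx as nx

__all__ = [
    "SignedNetwork",
    "NetworkValidationError",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "write_gml",
    "remove_node_and_edges",
]


class NetworkValidationError(ValueError):
    """An edge or node violates the signed-network invariants."""


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


def _validate_weight(u: str, v: str, w: float) -> float:
    w = float(w)
    if math.isnan(w) or not -1.0 <= w <= 1.0:
        raise NetworkValidationError(
            f"edge ({u}, {v}): weight {w!r} outside [-1, 1]"
        )
    if w == 0.0:
        raise NetworkValidationError(
            f"edge ({u}, {v}): zero weight is indistinguishable from no edge"
        )
    return w


class SignedNetwork:
    """Undirected network with signed weights in [-1, 1] \\ {0}.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples, or a mapping from
        unordered node pairs to weights.
    nodes
        Extra (possibly isolated) node identifiers.

    Raises
    ------
    NetworkValidationError
        On self-loops, out-of-range or zero weights, or duplicate edges
        with conflicting weights.
    """

    __slots__ = ("_g",)

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] | Mapping[tuple[str, str], float] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        for n in nodes:
            g.add_node(str(n))
        if isinstance(edges, Mapping):
            edges = [(u, v, w) for (u, v), w in edges.items()]
        for u, v, w in edges:
            u, v = str(u), str(v)
            if u == v:
                raise NetworkValidationError(f"self-loop on node {u!r}")
            w = _validate_weight(u, v, w)
            if g.has_edge(u, v) and g[u][v]["weight"] != w:
                raise NetworkValidationError(
                    f"duplicate edge ({u}, {v}) with conflicting weights "
                    f"{g[u][v]['weight']!r} and {w!r}"
                )
            g.add_edge(u, v, weight=w)
        self._g = g

    # -- container protocol -------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in lexicographic order."""
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as ``(u, v, weight)`` with u < v, sorted."""
        return sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self._g.edges(data=True)
        )

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"SignedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        """Signed weight of edge (u, v); symmetric lookup."""
        try:
            return self._g[u][v]["weight"]
        except KeyError:
            raise KeyError(f"no edge ({u}, {v})") from None

    def neighbors(self, node: str) -> list[str]:
        """Neighbors of ``node`` in lexicographic order."""
        return sorted(self._g.neighbors(node))

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def to_networkx(self) -> nx.Graph:
        """A defensive copy as a plain :class:`networkx.Graph`."""
        return self._g.copy()

    def copy(self) -> "SignedNetwork":
        new = SignedNetwork.__new__(SignedNetwork)
        new._g = self._g.copy()
        return new

    def subgraph_is_connected(self, nodes: Iterable[str]) -> bool:
        """True iff ``nodes`` induce a connected subgraph (singletons count)."""
        sub = self._g.subgraph(list(nodes))
        return sub.number_of_nodes() > 0 and nx.is_connected(sub)


# -- I/O --------------------------------------------------------------------


def read_edge_list(path: str, delimiter: str = "\t") -> SignedNetwork:
    """Parse a delimited edge list into a :class:`SignedNetwork`.

    Format: one edge per line as ``source<delim>target<delim>weight``;
    lines starting with ``#`` are comments; a single-field line declares
    an isolated node.  The file is undirected: ``a b w`` and ``b a w``
    name the same edge (repeating it with an equal weight is tolerated,
    with a conflicting weight is an error).
    """
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) == 1:
                nodes.append(fields[0].strip())
                continue
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 1 or 3 fields, got {len(fields)}"
                )
            u, v, w_str = (f.strip() for f in fields)
            try:
                w = float(w_str)
            except ValueError:
                raise EdgeListParseError(
                    f"{path}:{lineno}: weight {w_str!r} is not a number"
                ) from None
            try:
                _validate_weight(u, v, w)
                if u == v:
                    raise NetworkValidationError(f"self-loop on node {u!r}")
            except NetworkValidationError as exc:
                raise NetworkValidationError(f"{path}:{lineno}: {exc}") from None
            edges.append((u, v, w))
    return SignedNetwork(edges, nodes)


def write_edge_list(g: SignedNetwork, path: str, delimiter: str = "\t") -> None:
    """Write ``g`` as a delimited edge list (lossless round-trip).

    Weights are serialised with :func:`repr` so that
    ``read_edge_list(write_edge_list(g))`` reproduces ``g`` exactly.
    Isolated nodes are written as single-field lines.
    """
    covered: set[str] = set()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# signed edge list: source, target, weight in [-1,1]\n")
        for u, v, w in g.edges():
            fh.write(f"{u}{delimiter}{v}{delimiter}{w!r}\n")
            covered.add(u)
            covered.add(v)
        for n in g.nodes:
            if n not in covered:
                fh.write(f"{n}\n")


def read_gml(path: str) -> SignedNetwork:
    """Read a GML file (edges must carry a ``weight`` attribute)."""
    g = nx.read_gml(path)
    edges = []
    for u, v, d in g.edges(data=True):
        if "weight" not in d:
            raise NetworkValidationError(f"GML edge ({u}, {v}) has no weight")
        edges.append((str(u), str(v), float(d["weight"])))
    return SignedNetwork(edges, (str(n) for n in g.nodes))


def write_gml(g: SignedNetwork, path: str) -> None:
    nx.write_gml(g.to_networkx(), path)


def remove_node_and_edges(
    g: SignedNetwork, node: str, extra_edges: Iterable[tuple[str, str]] = ()
) -> SignedNetwork:
    """Return a copy of ``g`` without ``node``, its incident edges, and
    every edge in ``extra_edges``.

    The input network is left untouched (value semantics).  Endpoints of
    removed extra edges stay in the network even if isolated.
    """
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    new = g.copy()
    for u, v in extra_edges:
        if not new._g.has_edge(u, v):
            raise KeyError(f"edge ({u}, {v}) not in network")
        new._g.remove_edge(u, v)
    new._g.remove_node(node)
    return new
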