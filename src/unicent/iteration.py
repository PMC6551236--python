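"""Iterative centrality: extract, remove dependencies, recompute.

The loop that de-biases any centrality backbone: compute centralities
on the current network, take the most central node m, remove m together
with every *stable-triad* edge through m, and recompute, until every
remaining centrality is (numerically) zero.  Structural-balance theory
holds that two nodes joined to a mutual friend or mutual enemy — a
triangle with zero or exactly two negative edges — tend to be
associated *because of* that mutual neighbour, so once m is credited
with the association, the edge between its two partners is treated as
coincidental and removed with it.

The discovery order is the backbone's iterative ranking: position 1 is
the most central node of the original network, position 2 the most
central after m's dependencies are gone, and so on.  Nodes never
discovered are "unimportant" to this backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .backbones import compute_backbone
from .graph import SignedNetwork, remove_node_and_edges
from .paths import EXACT_MAX_NODES

__all__ = [
    "DiscoveryTrace",
    "stable_triad_edges",
    "iterate",
    "write_trace_tsv",
    "read_trace_tsv",
    "DEFAULT_ZERO_TOL",
]

#: centralities at or below this are treated as zero ("unimportant")
DEFAULT_ZERO_TOL = 1e-9


@dataclass
class DiscoveryTrace:
    """One backbone's ordered discoveries on one network.

    ``discovered[r - 1]`` is the node of rank r (1 = most central);
    ``per_iteration_removed_edges[r - 1]`` holds the stable-triad edges
    removed together with it.
    """

    backbone_name: str
    discovered: list[str] = field(default_factory=list)
    per_iteration_removed_edges: list[set[tuple[str, str]]] = field(default_factory=list)

    @property
    def discovered_set(self) -> set[str]:
        return set(self.discovered)

    def rank_of(self, node: str) -> int:
        """1-based discovery rank; raises if the node was not discovered."""
        try:
            return self.discovered.index(node) + 1
        except ValueError:
            raise KeyError(
                f"node {node!r} was not discovered by backbone {self.backbone_name}"
            ) from None


def stable_triad_edges(g: SignedNetwork, m: str) -> set[tuple[str, str]]:
    """Edges (B, C) forming a stable triad with ``m``.

    A triangle m-B-C is *stable* when it has zero or exactly two
    negative edges (balanced in the structural-balance sense: B and C
    share a mutual friend or a mutual enemy).  The returned pairs are
    ordered ``(min, max)``.
    """
    if m not in g:
        raise KeyError(f"node {m!r} not in network")
    nbrs = g.neighbors(m)
    out: set[tuple[str, str]] = set()
    for i, b in enumerate(nbrs):
        for c in nbrs[i + 1:]:
            if not g.has_edge(b, c):
                continue
            negatives = sum(
                1 for w in (g.weight(m, b), g.weight(m, c), g.weight(b, c)) if w < 0
            )
            if negatives in (0, 2):
                out.add((b, c) if b <= c else (c, b))
    return out


def iterate(
    g: SignedNetwork,
    backbone: str,
    zero_tol: float = DEFAULT_ZERO_TOL,
    path_method: str = "auto",
    progress: Callable[[str, int, str, int], None] | None = None,
) -> DiscoveryTrace:
    """Run the iterative loop for one backbone and return its trace.

    The path-search mode is resolved once from the *initial* network
    size, so a single run uses one algorithm throughout even as the
    network shrinks.  ``progress``, if given, is called per iteration
    with (backbone, iteration index, picked node, number of extra edges
    removed).  The input network is never modified.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    if path_method == "auto":
        path_method = "exact" if g.n_nodes <= EXACT_MAX_NODES else "fast"
    trace = DiscoveryTrace(backbone_name=backbone)
    current = g
    for iteration in range(g.n_nodes):
        if current.n_nodes == 0:
            break
        cv = compute_backbone(backbone, current, path_method=path_method)
        node, top = cv.argmax()
        if top <= zero_tol:
            break
        extra = stable_triad_edges(current, node)
        current = remove_node_and_edges(current, node, extra)
        trace.discovered.append(node)
        trace.per_iteration_removed_edges.append(extra)
        if progress is not None:
            progress(backbone, iteration + 1, node, len(extra))
    return trace


def write_trace_tsv(trace: DiscoveryTrace, path: str) -> None:
    """Write a discovery trace as TSV columns (backbone, rank, node)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("backbone\trank\tnode\n")
        for rank, node in enumerate(trace.discovered, start=1):
            fh.write(f"{trace.backbone_name}\t{rank}\t{node}\n")


def read_trace_tsv(path: str) -> DiscoveryTrace:
    """Read a trace written by :func:`write_trace_tsv` (edge removals
    are not serialised and come back empty)."""
    rows: list[tuple[int, str]] = []
    backbone = None
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "backbone\trank\tnode":
            raise ValueError(f"{path}: not a trace TSV (bad header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            name, rank, node = line.rstrip("\n").split("\t")
            if backbone is None:
                backbone = name
            elif name != backbone:
                raise ValueError(f"{path}:{lineno}: mixed backbone names")
            rows.append((int(rank), node))
    rows.sort()
    if [r for r, _ in rows] != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: ranks are not 1..n")
    return DiscoveryTrace(
        backbone_name=backbone or "?",
        discovered=[n for _, n in rows],
        per_iteration_removed_edges=[set() for _ in rows],
    )
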