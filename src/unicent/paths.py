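"""Signed maximum edge-weight-product path labels.

For a pair of nodes (i, j) in a signed network, the *gain* G(i, j) is
the maximum product of edge weights over simple paths from i to j whose
product is positive, and the *loss* L(i, j) is the minimum (most
negative) product over simple paths whose product is negative; both are
0 when no such path exists.  Because every |w| <= 1, extending a path
never increases the product magnitude, so strong paths are short and a
best-first search settles quickly.

Two search strategies are provided behind one interface:

``exact``
    A best-first search keeping, per (node, sign) state, a Pareto
    frontier of labels ``(magnitude, visited set)``: a label is
    discarded only when another label at the same state has magnitude
    at least as large and a visited set contained in the candidate's —
    then every simple extension of the candidate is matched or beaten
    by the same extension of the dominating label.  This is exact over
    *simple* paths.  The frontier can grow combinatorially on dense
    networks, so this mode suits small and moderate networks.

``fast``
    The classic signed Dijkstra variant: a single settled label per
    (node, sign), relaxed through each edge with a sign flip on
    negative edges, never revisiting a node already on the label's own
    path.  Near-linear-time, but it can miss an optimum when its only
    best path to an intermediate node already passes through the
    target.  This is the approximation suited to larger networks where
    the exact frontier is unaffordable.

``auto`` (the default) picks ``exact`` up to
:data:`EXACT_MAX_NODES` nodes and ``fast`` above.

Ties in magnitude are broken deterministically in both modes: fewer
edges first, then the lexicographically smallest node sequence.  The
recorded witness paths drive signed betweenness counting, so this
order matters.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .graph import SignedNetwork

__all__ = [
    "PathLabels",
    "mod_dijkstra",
    "all_pairs_labels",
    "brute_force_labels",
    "EXACT_MAX_NODES",
]

#: pairs whose magnitudes differ by less than this (relative) are co-optimal
MAGNITUDE_RTOL = 1e-9

#: ``auto`` method switches from exact to fast search above this size
EXACT_MAX_NODES = 30

_BRUTE_FORCE_MAX_NODES = 10


def _pair(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass
class PathLabels:
    """Best positive (G) and negative (L) path products per node pair.

    Maps are keyed by unordered pairs ``(min(i, j), max(i, j))``; absent
    pairs have G = L = 0 and empty witnesses.  Witness paths are simple
    node sequences realising the label value, stored oriented from the
    lexicographically smaller endpoint.
    """

    nodes: list[str]
    G: dict[tuple[str, str], float] = field(default_factory=dict)
    L: dict[tuple[str, str], float] = field(default_factory=dict)
    witness_pos: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    witness_neg: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def gain(self, i: str, j: str) -> float:
        return self.G.get(_pair(i, j), 0.0)

    def loss(self, i: str, j: str) -> float:
        return self.L.get(_pair(i, j), 0.0)

    def pos_witness(self, i: str, j: str) -> tuple[str, ...]:
        return self.witness_pos.get(_pair(i, j), ())

    def neg_witness(self, i: str, j: str) -> tuple[str, ...]:
        return self.witness_neg.get(_pair(i, j), ())


def _index_adjacency(g: SignedNetwork) -> tuple[list[str], list[list[tuple[int, float]]]]:
    names = g.nodes  # lexicographically sorted
    index = {name: i for i, name in enumerate(names)}
    adj: list[list[tuple[int, float]]] = [[] for _ in names]
    for u, v, w in g.edges():
        adj[index[u]].append((index[v], w))
        adj[index[v]].append((index[u], w))
    for lst in adj:
        lst.sort()
    return names, adj


def _reachable_states(adj: list[list[tuple[int, float]]], source: int) -> set[tuple[int, int]]:
    """States (node, sign) reachable from (source, +) in the sign-lift graph."""
    seen = {(source, 0)}
    stack = [(source, 0)]
    while stack:
        node, sign = stack.pop()
        for nbr, w in adj[node]:
            nstate = (nbr, sign ^ (1 if w < 0 else 0))
            if nstate not in seen:
                seen.add(nstate)
                stack.append(nstate)
    return seen


def _walk_bound(adj: list[list[tuple[int, float]]], source: int) -> list[float]:
    """Max product magnitude over *walks* from ``source`` (upper bound on
    any simple-path label magnitude; plain max-product Dijkstra)."""
    n = len(adj)
    bound = [0.0] * n
    bound[source] = 1.0
    heap = [(-1.0, source)]
    done = [False] * n
    while heap:
        negm, node = heapq.heappop(heap)
        if done[node]:
            continue
        done[node] = True
        m = -negm
        for nbr, w in adj[node]:
            nm = m * (w if w > 0 else -w)
            if nm > bound[nbr]:
                bound[nbr] = nm
                heapq.heappush(heap, (-nm, nbr))
    return bound


def _single_source_exact(
    adj: list[list[tuple[int, float]]],
    source: int,
    walk_bounds: list[list[float]] | None = None,
) -> dict[tuple[int, int], tuple[float, tuple[int, ...]]]:
    """Exact best-first search from ``source`` over simple paths.

    Returns ``{(target, sign): (magnitude, path)}`` where sign is 0 for
    positive products and 1 for negative.  Node indices must follow the
    lexicographic order of node names so tuple comparison on index paths
    matches the documented tie-break.

    Exactness argument: labels are popped in decreasing magnitude (ties:
    fewer edges, then lexicographic path), so the first pop of a state
    is its optimum provided the optimal path's every prefix survives
    pruning — and a prefix is pruned only in favour of a label whose
    every extension is at least as good with the same or better
    tie-break.  The search stops once every reachable state is settled.
    """
    n = len(adj)
    if walk_bounds is None:
        walk_bounds = [_walk_bound(adj, u) for u in range(n)]
    reachable = _reachable_states(adj, source)
    # lift-reachability over-approximates simple-path reachability; the
    # source's own states can never be settled by a simple path
    unsettled = {(t, s) for (t, s) in reachable if t != source}
    # Pareto frontier per state: list of (mag, visited_mask, length, path)
    pareto: list[list[tuple[float, int, int, tuple[int, ...]]]] = [
        [] for _ in range(2 * n)
    ]
    # running lower bound on each state's final value (any recorded label
    # is a realizable simple path)
    lb = [0.0] * (2 * n)
    best: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
    start = (1.0, 1 << source, 0, (source,))
    pareto[2 * source].append(start)
    heap: list[tuple[float, int, tuple[int, ...], int, int, int, float]] = [
        (-1.0, 0, (source,), source, 0, 1 << source, 1.0)
    ]
    while heap and unsettled:
        _, length, path, node, sign, visited, mag = heapq.heappop(heap)
        state = 2 * node + sign
        entry = (mag, visited, length, path)
        if entry not in pareto[state]:
            continue  # superseded after being queued
        key = (node, sign)
        if key in unsettled:
            best[key] = (mag, path)
            unsettled.discard(key)
            if not unsettled:
                break
        # discard labels that provably cannot beat any still-unsettled
        # state: mag * walk-bound(node -> t) < that state's lower bound
        wb = walk_bounds[node]
        useful = False
        for t, s in unsettled:
            if not (visited >> t) & 1 and mag * wb[t] >= lb[2 * t + s]:
                useful = True
                break
        if not useful:
            continue
        for nbr, w in adj[node]:
            bit = 1 << nbr
            if visited & bit:
                continue
            nmag = mag * (w if w > 0 else -w)
            nsign = sign ^ (1 if w < 0 else 0)
            nvis = visited | bit
            nlen = length + 1
            npath = path + (nbr,)
            nstate = 2 * nbr + nsign
            frontier = pareto[nstate]
            dominated = False
            for m2, vis2, l2, p2 in frontier:
                if vis2 & nvis == vis2 and (
                    m2 > nmag or (m2 == nmag and (l2, p2) <= (nlen, npath))
                ):
                    dominated = True
                    break
            if dominated:
                continue
            pareto[nstate] = [
                lab
                for lab in frontier
                if not (
                    lab[1] & nvis == nvis
                    and (nmag > lab[0] or (nmag == lab[0] and (nlen, npath) <= lab[2:]))
                )
            ]
            pareto[nstate].append((nmag, nvis, nlen, npath))
            if nmag > lb[nstate]:
                lb[nstate] = nmag
            heapq.heappush(heap, (-nmag, nlen, npath, nbr, nsign, nvis, nmag))
    return best


def _single_source_fast(
    adj: list[list[tuple[int, float]]], source: int
) -> dict[tuple[int, int], tuple[float, tuple[int, ...]]]:
    """Single-label-per-state signed Dijkstra (the fast approximation).

    Keeps one settled label per (node, sign), relaxing both signs
    through every edge and never revisiting a node already on the
    label's own path.  Same return shape and tie-break as the exact
    search; may under-estimate a label when every best path to an
    intermediate node blocks the target.
    """
    settled: set[int] = set()
    best: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, int, tuple[int, ...], int, int, int, float]] = [
        (-1.0, 0, (source,), source, 0, 1 << source, 1.0)
    ]
    while heap:
        _, length, path, node, sign, visited, mag = heapq.heappop(heap)
        state = 2 * node + sign
        if state in settled:
            continue
        settled.add(state)
        if node != source:
            best[(node, sign)] = (mag, path)
        for nbr, w in adj[node]:
            bit = 1 << nbr
            if visited & bit:
                continue
            nsign = sign ^ (1 if w < 0 else 0)
            if 2 * nbr + nsign in settled:
                continue
            nmag = mag * (w if w > 0 else -w)
            heapq.heappush(
                heap, (-nmag, length + 1, path + (nbr,), nbr, nsign, visited | bit, nmag)
            )
    return best


def _resolve_method(method: str, n_nodes: int) -> str:
    if method == "auto":
        return "exact" if n_nodes <= EXACT_MAX_NODES else "fast"
    if method not in ("exact", "fast"):
        raise ValueError(f"unknown search method {method!r}")
    return method


def mod_dijkstra(g: SignedNetwork, source: str, method: str = "auto") -> PathLabels:
    """Signed max-product path labels from ``source`` to every node.

    Returns a :class:`PathLabels` whose maps contain only pairs
    ``(source, *)``.  G is the best positive product over simple paths,
    L the most negative product; 0 (absent) where no such path exists.
    """
    if source not in g:
        raise KeyError(f"source node {source!r} not in network")
    names, adj = _index_adjacency(g)
    source_idx = names.index(source)
    search = (
        _single_source_exact
        if _resolve_method(method, len(names)) == "exact"
        else _single_source_fast
    )
    best = search(adj, source_idx)
    labels = PathLabels(nodes=names)
    src = names[source_idx]
    for (t, sign), (mag, path) in best.items():
        key = _pair(src, names[t])
        walk = tuple(names[i] for i in path)
        if walk[0] != key[0]:
            walk = walk[::-1]
        if sign == 0:
            labels.G[key] = mag
            labels.witness_pos[key] = walk
        else:
            labels.L[key] = -mag
            labels.witness_neg[key] = walk
    return labels


def all_pairs_labels(g: SignedNetwork, method: str = "auto") -> PathLabels:
    """Run the single-source search from every node and merge results.

    Each unordered pair is recorded from its lexicographically smaller
    endpoint's run, which fixes the witness orientation; symmetry of the
    values themselves is a property of the path definition.
    """
    names, adj = _index_adjacency(g)
    resolved = _resolve_method(method, len(names))
    labels = PathLabels(nodes=names)
    walk_bounds = (
        [_walk_bound(adj, u) for u in range(len(names))] if resolved == "exact" else None
    )
    for source_idx in range(len(names)):
        if resolved == "exact":
            best = _single_source_exact(adj, source_idx, walk_bounds)
        else:
            best = _single_source_fast(adj, source_idx)
        # keep only targets above the source: the pair is canonical there
        for (t, sign), (mag, path) in best.items():
            if t < source_idx:
                continue
            key = (names[source_idx], names[t])
            walk = tuple(names[i] for i in path)
            if sign == 0:
                labels.G[key] = mag
                labels.witness_pos[key] = walk
            else:
                labels.L[key] = -mag
                labels.witness_neg[key] = walk
    return labels


def brute_force_labels(g: SignedNetwork) -> PathLabels:
    """Exhaustive simple-path enumeration oracle (networks of <= 10 nodes).

    Definitionally correct and exponential: enumerates every simple path
    between every pair, tracking the best positive and most negative
    product with the same (fewest edges, lexicographic) tie-break as the
    search.  Used to verify :func:`all_pairs_labels`, never to replace it.
    """
    if g.n_nodes > _BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute-force enumeration refused: {g.n_nodes} nodes "
            f"(limit {_BRUTE_FORCE_MAX_NODES})"
        )
    names, adj = _index_adjacency(g)
    labels = PathLabels(nodes=names)
    n = len(names)
    for source_idx in range(n):
        best: dict[tuple[int, int], tuple[float, int, tuple[int, ...]]] = {}

        def dfs(node: int, visited: int, prod: float, path: tuple[int, ...]) -> None:
            if node > source_idx:
                sign = 0 if prod > 0 else 1
                mag = abs(prod)
                key = (node, sign)
                cand = (mag, len(path) - 1, path)
                cur = best.get(key)
                if cur is None or (-mag, cand[1], path) < (-cur[0], cur[1], cur[2]):
                    best[key] = cand
            for nbr, w in adj[node]:
                bit = 1 << nbr
                if visited & bit:
                    continue
                dfs(nbr, visited | bit, prod * w, path + (nbr,))

        dfs(source_idx, 1 << source_idx, 1.0, (source_idx,))
        for (t, sign), (mag, _, path) in best.items():
            key = (names[source_idx], names[t])
            walk = tuple(names[i] for i in path)
            if sign == 0:
                labels.G[key] = mag
                labels.witness_pos[key] = walk
            else:
                labels.L[key] = -mag
                labels.witness_neg[key] = walk
    return labels
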