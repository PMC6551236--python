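"""Shared fixtures and an independent oracle simulation.

The oracle functions below re-derive signed path products, the three
backbone centralities and the iterative discovery loop directly on a
:class:`networkx.Graph` with exhaustive simple-path enumeration.  They
deliberately share no code with the package internals so that golden
tests check the implementation against an independent reading of the
method, not against itself.  They are exponential and only usable on
tiny networks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from unicent import SignedNetwork
from unicent.synthetic import random_test_network


@pytest.fixture
def toy_path():
    """a-b (0.8), b-c (-0.5): the canonical mixed-sign 3-node path."""
    return SignedNetwork([("a", "b", 0.8), ("b", "c", -0.5)])


def make_random_network(seed: int, n: int = 8, p: float = 0.4,
                        mags=(0.05, 0.95), neg: float = 0.5) -> SignedNetwork:
    return random_test_network(n, p, mags, neg, seed=seed)


# -- independent oracle -----------------------------------------------------


def oracle_path_products(g: nx.Graph):
    """Exhaustive best positive / most negative simple-path products.

    Returns {(i, j): {True: (-mag, n_edges, path), False: ...}} with
    True = positive product; the canonical witness minimises
    (-magnitude, edge count, node sequence).
    """
    out = {}
    for i, j in itertools.combinations(sorted(g.nodes), 2):
        best = {}
        for path in nx.all_simple_paths(g, i, j):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= g[a][b]["weight"]
            sign = prod > 0
            cand = (-abs(prod), len(path) - 1, tuple(path))
            if sign not in best or cand < best[sign]:
                best[sign] = cand
        out[(i, j)] = best
    return out


def oracle_centrality(g: nx.Graph, kind: str) -> dict[str, float]:
    vals = {n: 0.0 for n in g.nodes}
    if kind == "DEG":
        for n in g.nodes:
            vals[n] = abs(sum(g[n][m]["weight"] for m in g.neighbors(n)))
        return vals
    pp = oracle_path_products(g)
    if kind == "CLO":
        for (i, j), best in pp.items():
            tot = 0.0
            if True in best:
                tot += -best[True][0]
            if False in best:
                tot += best[False][0]  # stored as -magnitude = the value
            vals[i] += tot
            vals[j] += tot
        return {n: abs(v) for n, v in vals.items()}
    if kind == "BET":
        for best in pp.values():
            for sign in best:
                for interior in best[sign][2][1:-1]:
                    vals[interior] += 1.0
        return vals
    raise ValueError(kind)


def oracle_iterate(g: nx.Graph, kind: str, tol: float = 1e-9) -> list[str]:
    """Straightforward re-simulation of the iterative loop."""
    g = g.copy()
    order = []
    while g.number_of_nodes():
        vals = oracle_centrality(g, kind)
        top = max(vals.values())
        if top <= tol:
            break
        m = min(n for n, v in vals.items() if v == top)
        order.append(m)
        for b, c in itertools.combinations(sorted(g.neighbors(m)), 2):
            if g.has_edge(b, c):
                negs = sum(
                    1
                    for w in (g[m][b]["weight"], g[m][c]["weight"], g[b][c]["weight"])
                    if w < 0
                )
                if negs in (0, 2):
                    g.remove_edge(b, c)
        g.remove_node(m)
    return order
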