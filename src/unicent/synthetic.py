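"""Seeded generators for signed weighted test networks.

Two topology families emulate the inputs the method is aimed at:

``modular``
    A planted-partition network resembling a microbial co-occurrence
    network: dense, mostly positive edges inside modules; sparse,
    mixed-sign edges between modules; one designated hub per module
    wired to every other member of its module with a strong positive
    weight.  Hubs are the planted "central" nodes.

``scale_free``
    A preferential-attachment (Barabási–Albert) skeleton with signed
    weights sampled independently per edge, resembling the heavy-tailed
    degree distributions of large interaction networks.

``path`` and ``star`` are tiny deterministic topologies for tests, and
``fixture`` names a catalogue of hand-built networks with verified
expected outcomes (see :func:`fixture`).

All generators are deterministic: the same :class:`GeneratorSpec`
(including seed) yields a byte-for-byte identical network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import SignedNetwork

__all__ = ["GeneratorSpec", "generate", "fixture", "FIXTURE_NAMES"]

_TOPOLOGIES = ("modular", "scale_free", "path", "star", "fixture")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic signed network.

    Defaults describe a mid-sized co-occurrence-like network: 5 modules
    whose internal edges are dense and mostly positive (a small fraction
    of co-exclusions), inter-module edges sparse and half negative.
    Weight magnitudes are uniform on the given intervals.
    """

    n_nodes: int = 126
    topology: str = "modular"
    n_modules: int = 5
    p_in: float = 0.4
    p_out: float = 0.03
    pos_weight_range: tuple[float, float] = (0.2, 0.9)
    neg_weight_range: tuple[float, float] = (0.2, 0.9)
    neg_fraction_in: float = 0.15
    neg_fraction_out: float = 0.5
    hub_weight_range: tuple[float, float] = (0.75, 0.95)
    plant_hubs: bool = True
    attachment: int = 2  # edges per new node (scale_free)
    neg_fraction: float = 0.3  # sign fraction (scale_free)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; expected one of {_TOPOLOGIES}"
            )
        if self.topology == "modular" and not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")
        for p in (self.p_in, self.p_out, self.neg_fraction_in, self.neg_fraction_out, self.neg_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.pos_weight_range, self.neg_weight_range, self.hub_weight_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"weight magnitude range ({lo}, {hi}) not within (0, 1]")


def _node_name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def _sample_weight(rng: np.random.Generator, mag_range: tuple[float, float], negative: bool) -> float:
    mag = float(rng.uniform(*mag_range))
    return -mag if negative else mag


def _generate_modular(spec: GeneratorSpec, rng: np.random.Generator) -> SignedNetwork:
    width = len(str(spec.n_nodes - 1))
    names = [_node_name(i, width) for i in range(spec.n_nodes)]
    module_of = {names[i]: i % spec.n_modules for i in range(spec.n_nodes)}
    modules: list[list[str]] = [[] for _ in range(spec.n_modules)]
    for name in names:
        modules[module_of[name]].append(name)
    edges: dict[tuple[str, str], float] = {}
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            same = module_of[u] == module_of[v]
            p = spec.p_in if same else spec.p_out
            if rng.random() >= p:
                continue
            neg = rng.random() < (spec.neg_fraction_in if same else spec.neg_fraction_out)
            rng_range = spec.neg_weight_range if neg else spec.pos_weight_range
            edges[(u, v)] = _sample_weight(rng, rng_range, neg)
    if spec.plant_hubs:
        for members in modules:
            if len(members) < 2:
                continue
            hub = members[0]
            for other in members[1:]:
                key = (hub, other) if hub < other else (other, hub)
                edges[key] = _sample_weight(rng, spec.hub_weight_range, False)
    return SignedNetwork(((u, v, w) for (u, v), w in edges.items()), names)


def _generate_scale_free(spec: GeneratorSpec, rng: np.random.Generator) -> SignedNetwork:
    m = min(spec.attachment, max(1, spec.n_nodes - 1))
    skeleton = nx.barabasi_albert_graph(
        spec.n_nodes, m, seed=int(rng.integers(0, 2**31 - 1))
    )
    width = len(str(spec.n_nodes - 1))
    edges = []
    for u, v in sorted(skeleton.edges()):
        neg = rng.random() < spec.neg_fraction
        w = _sample_weight(rng, spec.neg_weight_range if neg else spec.pos_weight_range, neg)
        edges.append((_node_name(u, width), _node_name(v, width), w))
    names = [_node_name(i, width) for i in range(spec.n_nodes)]
    return SignedNetwork(edges, names)


def _generate_path(spec: GeneratorSpec, rng: np.random.Generator) -> SignedNetwork:
    width = len(str(spec.n_nodes - 1))
    names = [_node_name(i, width) for i in range(spec.n_nodes)]
    edges = []
    for u, v in zip(names, names[1:]):
        neg = rng.random() < spec.neg_fraction
        w = _sample_weight(rng, spec.neg_weight_range if neg else spec.pos_weight_range, neg)
        edges.append((u, v, w))
    return SignedNetwork(edges, names)


def _generate_star(spec: GeneratorSpec, rng: np.random.Generator) -> SignedNetwork:
    width = len(str(spec.n_nodes - 1))
    names = [_node_name(i, width) for i in range(spec.n_nodes)]
    edges = []
    for leaf in names[1:]:
        neg = rng.random() < spec.neg_fraction
        w = _sample_weight(rng, spec.neg_weight_range if neg else spec.pos_weight_range, neg)
        edges.append((names[0], leaf, w))
    return SignedNetwork(edges, names)


def generate(spec: GeneratorSpec) -> SignedNetwork:
    """Generate a signed network from a validated :class:`GeneratorSpec`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "modular":
        return _generate_modular(spec, rng)
    if spec.topology == "scale_free":
        return _generate_scale_free(spec, rng)
    if spec.topology == "path":
        return _generate_path(spec, rng)
    if spec.topology == "star":
        return _generate_star(spec, rng)
    raise ValueError("topology 'fixture' requires fixture(name)")


def random_test_network(
    n_nodes: int,
    edge_prob: float = 0.4,
    weight_magnitudes: tuple[float, float] = (0.05, 0.95),
    neg_fraction: float = 0.5,
    seed: int = 0,
) -> SignedNetwork:
    """Erdős–Rényi-style signed network used by verification ensembles."""
    rng = np.random.default_rng(seed)
    width = len(str(max(n_nodes - 1, 1)))
    names = [_node_name(i, width) for i in range(n_nodes)]
    edges = []
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            if rng.random() < edge_prob:
                neg = rng.random() < neg_fraction
                edges.append((u, v, _sample_weight(rng, weight_magnitudes, neg)))
    return SignedNetwork(edges, names)


# -- fixture catalogue ------------------------------------------------------
# Hand-built networks with expected outcomes used by golden tests.  Each
# fixture's expectations were verified by an independent simulation of
# the iterative loop over brute-force path labels (see tests), not by
# the code under test.  Populated in fixtures.py to keep this module
# focused on generators.

from .fixtures import FIXTURE_NAMES, fixture  # noqa: E402,F401
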