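"""Signed path-based centrality indices behind a pluggable registry.

Three built-in *backbones* operate on a signed network:

* ``CLO`` — signed closeness: ``|sum_j G(i, j) + L(i, j)|``, the absolute
  net benefit node i draws from every other node through its best
  positive (gain) and best negative (loss) path products.
* ``DEG`` — signed degree: ``|sum_j W(i, j)|`` over incident edges; a
  node whose positive and negative attachments cancel is as peripheral
  as an isolated one.
* ``BET`` — signed betweenness: the number of recorded maximum positive
  and maximum-magnitude negative witness paths, over all node pairs, on
  which i is an interior node.  One deterministic witness per (pair,
  sign) keeps the count well-defined when several co-optimal paths
  exist; endpoints do not count as "on" a path.

Any other index can be registered by name and used by the iterative
loop and consensus stage, so a run may combine any k >= 2 algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .graph import SignedNetwork
from .paths import PathLabels, all_pairs_labels

__all__ = [
    "CentralityVector",
    "closeness_centrality",
    "degree_centrality",
    "betweenness_centrality",
    "register_backbone",
    "unregister_backbone",
    "registered_backbones",
    "compute_backbone",
    "BUILTIN_BACKBONES",
]


@dataclass
class CentralityVector:
    """Non-negative centrality values for every node of a network."""

    backbone_name: str
    values: dict[str, float]

    def argmax(self) -> tuple[str, float]:
        """The most central node; ties go to the lexicographically
        smallest identifier."""
        if not self.values:
            raise ValueError("empty centrality vector")
        top = max(self.values.values())
        node = min(n for n, v in self.values.items() if v == top)
        return node, top


def _check_labels(g: SignedNetwork, labels: PathLabels) -> None:
    if set(labels.nodes) != set(g.nodes):
        raise ValueError(
            "path labels were computed on a different node set than the network"
        )


def closeness_centrality(g: SignedNetwork, labels: PathLabels) -> CentralityVector:
    """Signed closeness: absolute sum of gains plus losses per node."""
    _check_labels(g, labels)
    totals = {n: 0.0 for n in g.nodes}
    for (i, j), gain in labels.G.items():
        totals[i] += gain
        totals[j] += gain
    for (i, j), loss in labels.L.items():
        totals[i] += loss
        totals[j] += loss
    return CentralityVector("CLO", {n: abs(t) for n, t in totals.items()})


def degree_centrality(g: SignedNetwork) -> CentralityVector:
    """Signed degree: absolute sum of incident signed weights."""
    values = {}
    for n in g.nodes:
        values[n] = abs(sum(g.weight(n, m) for m in g.neighbors(n)))
    return CentralityVector("DEG", values)


def betweenness_centrality(g: SignedNetwork, labels: PathLabels) -> CentralityVector:
    """Signed betweenness: witness-path interior membership counts.

    Requires witness paths in ``labels``; each unordered pair
    contributes at most one positive and one negative path.
    """
    _check_labels(g, labels)
    for key in labels.G:
        if key not in labels.witness_pos:
            raise ValueError(f"missing positive witness path for pair {key}")
    for key in labels.L:
        if key not in labels.witness_neg:
            raise ValueError(f"missing negative witness path for pair {key}")
    counts = {n: 0.0 for n in g.nodes}
    for witness_map in (labels.witness_pos, labels.witness_neg):
        for path in witness_map.values():
            for interior in path[1:-1]:
                counts[interior] += 1.0
    return CentralityVector("BET", counts)


# -- registry ---------------------------------------------------------------

_BackboneFn = Callable[[SignedNetwork, str], CentralityVector]
_REGISTRY: dict[str, _BackboneFn] = {}


def _clo(g: SignedNetwork, path_method: str) -> CentralityVector:
    return closeness_centrality(g, all_pairs_labels(g, method=path_method))


def _deg(g: SignedNetwork, path_method: str) -> CentralityVector:
    return degree_centrality(g)


def _bet(g: SignedNetwork, path_method: str) -> CentralityVector:
    return betweenness_centrality(g, all_pairs_labels(g, method=path_method))


BUILTIN_BACKBONES = ("BET", "CLO", "DEG")
_REGISTRY["BET"] = _bet
_REGISTRY["CLO"] = _clo
_REGISTRY["DEG"] = _deg


def register_backbone(name: str, fn: Callable[[SignedNetwork], CentralityVector]) -> None:
    """Register a custom centrality algorithm under ``name``.

    ``fn`` receives the network and must return a
    :class:`CentralityVector` with a value for every node.  The name
    then becomes usable wherever a backbone label is accepted.
    """
    if name in _REGISTRY:
        raise ValueError(f"backbone {name!r} is already registered")

    def wrapped(g: SignedNetwork, path_method: str) -> CentralityVector:
        return fn(g)

    _REGISTRY[name] = wrapped


def unregister_backbone(name: str) -> None:
    """Remove a previously registered custom backbone."""
    if name in BUILTIN_BACKBONES:
        raise ValueError(f"built-in backbone {name!r} cannot be unregistered")
    del _REGISTRY[name]


def registered_backbones() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def compute_backbone(
    name: str, g: SignedNetwork, path_method: str = "auto"
) -> CentralityVector:
    """Evaluate the backbone registered under ``name`` on ``g``."""
    try:
        fn = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {', '.join(registered_backbones())}"
        ) from None
    cv = fn(g, path_method)
    missing = set(g.nodes) - set(cv.values)
    if missing:
        raise ValueError(f"backbone {name!r} returned no value for nodes {sorted(missing)}")
    return cv
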