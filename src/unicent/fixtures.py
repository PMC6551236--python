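"""Hand-built fixture networks with annotated expected outcomes.

Each fixture is a small signed network whose consensus behaviour is
known in advance.  The expected traces and supernodes recorded here
were verified by an independent re-simulation of the iterative loop
over exhaustively enumerated simple paths (the golden tests repeat
that cross-check); they are not outputs of the code under test.

Catalogue
---------
``triad_tossup``
    Seven nodes; the three backbones each discover a different corner
    of the triangle n0-n3-n6, yielding exactly one size-3 supernode
    (a three-way toss-up) alongside one universal agreement (n4).
``adjacency_tossup``
    Six nodes; betweenness discovers n4 while closeness and degree
    both discover its neighbour n5, yielding exactly one size-2
    supernode.
``merge_chain``
    A symbolic topology (nodes named after the backbones that discover
    them, traces supplied with the fixture) in which one triad overlaps
    two adjacencies and the merged result overlaps a third, so merging
    must chain: triad + two adjacencies collapse into a supernode whose
    first position holds two alternative nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import SignedNetwork

__all__ = ["Fixture", "FIXTURE_NAMES", "fixture"]


@dataclass(frozen=True)
class Fixture:
    """A small network plus the outcome its golden test asserts."""

    name: str
    network: SignedNetwork
    expected: dict = field(default_factory=dict)
    #: discovery orders supplied with the fixture (symbolic fixtures only)
    traces: dict[str, list[str]] | None = None


def _triad_tossup() -> Fixture:
    network = SignedNetwork(
        [
            ("n0", "n3", 0.8654925326912646),
            ("n0", "n4", 0.36143672286531403),
            ("n0", "n6", -0.33861600255878777),
            ("n2", "n4", 0.24374016042203372),
            ("n3", "n6", -0.13679810797146832),
            ("n4", "n5", 0.793338092981076),
        ],
        nodes=[f"n{i}" for i in range(7)],
    )
    return Fixture(
        name="triad_tossup",
        network=network,
        expected={
            "traces": {"BET": ["n0", "n4"], "CLO": ["n4", "n6"], "DEG": ["n4", "n3"]},
            "agreed_important": {"n4"},
            "supernodes": [
                {
                    "positions": [{"n0"}, {"n6"}, {"n3"}],
                    "covered": [{"BET"}, {"CLO"}, {"DEG"}],
                }
            ],
            "unresolvable": set(),
            "unimportant": {"n1", "n2", "n5"},
        },
    )


def _adjacency_tossup() -> Fixture:
    network = SignedNetwork(
        [
            ("n0", "n2", -0.17469454365875628),
            ("n0", "n3", 0.6861212097143099),
            ("n1", "n2", 0.13795384573911829),
            ("n1", "n4", 0.12523612353434582),
            ("n1", "n5", 0.2244896616784856),
            ("n2", "n3", -0.42819554868119136),
            ("n2", "n5", 0.4073773698998807),
            ("n4", "n5", 0.468212931841237),
        ],
        nodes=[f"n{i}" for i in range(6)],
    )
    return Fixture(
        name="adjacency_tossup",
        network=network,
        expected={
            "traces": {"BET": ["n2", "n4"], "CLO": ["n5", "n2"], "DEG": ["n5", "n2"]},
            "agreed_important": {"n2"},
            "supernodes": [
                {"positions": [{"n4"}, {"n5"}], "covered": [{"BET"}, {"CLO", "DEG"}]}
            ],
            "unresolvable": set(),
            "unimportant": {"n0", "n1", "n3"},
        },
    )


def _merge_chain() -> Fixture:
    # topology only — the traces below are part of the fixture, so edge
    # weights are immaterial to the expected outcome
    network = SignedNetwork(
        [
            ("B3", "C5", 0.8),
            ("B3", "D2", 0.7),
            ("C5", "D2", 0.6),
            ("B3", "CD3", 0.5),
            ("B3", "CD4", 0.5),
            ("B4", "CD3", 0.9),
        ]
    )
    return Fixture(
        name="merge_chain",
        network=network,
        traces={
            "BET": ["B3", "B4"],
            "CLO": ["C5", "CD3", "CD4"],
            "DEG": ["D2", "CD3", "CD4"],
        },
        expected={
            "pre_merge": [
                {"positions": [{"B3"}, {"C5"}, {"D2"}],
                 "covered": [{"BET"}, {"CLO"}, {"DEG"}]},
                {"positions": [{"B3"}, {"CD3"}], "covered": [{"BET"}, {"CLO", "DEG"}]},
                {"positions": [{"B3"}, {"CD4"}], "covered": [{"BET"}, {"CLO", "DEG"}]},
                {"positions": [{"B4"}, {"CD3"}], "covered": [{"BET"}, {"CLO", "DEG"}]},
            ],
            "merged": [
                {
                    "positions": [
                        {"B3", "B4"},
                        {"C5", "CD3", "CD4"},
                        {"D2", "CD3", "CD4"},
                    ],
                    "covered": [{"BET"}, {"CLO"}, {"DEG"}],
                }
            ],
            "merged_score": 1.0,
        },
    )


def _build_catalogue() -> dict[str, Fixture]:
    catalogue = {}
    for build in (_triad_tossup, _adjacency_tossup, _merge_chain):
        fx = build()
        catalogue[fx.name] = fx
    return catalogue


_CATALOGUE = _build_catalogue()
FIXTURE_NAMES = tuple(sorted(_CATALOGUE))


def fixture(name: str) -> Fixture:
    """Return a catalogued fixture network with its expected outcomes."""
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; catalogue: {', '.join(FIXTURE_NAMES)}"
        ) from None
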