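"""Consensus over iterative backbones: agreements, supernodes, ranking.

Given the discovery traces of k >= 2 iterative backbones on the same
network, the consensus stage produces one unified ranked set:

1. *Universal agreements* — nodes every backbone discovered — enter the
   ranked set directly.
2. Among the remaining disagreement nodes, *supernodes* are detected: a
   connected set of 2..k nodes whose discovering-backbone sets are
   pairwise disjoint and together cover every backbone exactly once.
   Iteration makes such a set a centrality "toss-up": whichever member
   is extracted first strips the others of the shared contribution.
3. Supernodes sharing a member are *merged* into one supernode whose
   positions may hold several alternative nodes, by aligning positions
   on the backbones they cover (the common refinement of the two
   backbone partitions).  A merge whose two backbone partitions do not
   nest cell-by-cell has no defined outcome and is reported unmerged.
4. Disagreement nodes absorbed by no supernode are flagged
   *unresolvable*; nodes discovered by no backbone are *unimportant*.
5. Elements are scored by mean discovery rank (each supernode position
   is scored under the backbones covering it, an alternative set by its
   earliest-discovered member) and sorted ascending.

The four classes — agreed important, supernode members, unresolvable,
unimportant — partition the node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import scipy.stats

from .graph import SignedNetwork
from .iteration import DEFAULT_ZERO_TOL, DiscoveryTrace, iterate

__all__ = [
    "Supernode",
    "RankedElement",
    "UnifiedRanking",
    "universal_agreements",
    "find_supernodes",
    "merge_supernodes",
    "rank_elements",
    "consensus_ranking",
    "expanded_rank_vector",
    "spearman",
    "write_ranking_tsv",
    "write_partition_json",
]


@dataclass(frozen=True)
class Supernode:
    """A toss-up set: one position per covered backbone group.

    ``positions[p]`` is the set of alternative base nodes at position p
    and ``covered[p]`` the backbones that position accounts for; each
    backbone is covered by exactly one position.  Positions are ordered
    by their (sorted) covered-backbone sets.
    """

    positions: tuple[frozenset[str], ...]
    covered: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.covered):
            raise ValueError("positions and covered backbone sets differ in length")
        seen: set[str] = set()
        for cov in self.covered:
            if not cov or seen & cov:
                raise ValueError("each backbone must be covered exactly once")
            seen |= cov

    @property
    def base_nodes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for pos in self.positions:
            out |= pos
        return out

    @property
    def backbone_set(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for cov in self.covered:
            out |= cov
        return out

    def sort_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.base_nodes))

    @classmethod
    def build(
        cls, groups: list[tuple[set[str] | frozenset[str], set[str] | frozenset[str]]]
    ) -> "Supernode":
        """Build from (members, covered backbones) pairs in any order."""
        ordered = sorted(groups, key=lambda mc: tuple(sorted(mc[1])))
        return cls(
            positions=tuple(frozenset(m) for m, _ in ordered),
            covered=tuple(frozenset(c) for _, c in ordered),
        )

    def describe(self) -> str:
        """Symbolic form, e.g. ``[a, {b,c}, {b,d}]``."""
        parts = []
        for pos in self.positions:
            members = sorted(pos)
            parts.append(members[0] if len(members) == 1 else "{" + ",".join(members) + "}")
        return "[" + ", ".join(parts) + "]"


@dataclass(frozen=True)
class RankedElement:
    """One entry of the unified ranking: a node or a supernode."""

    member: str | Supernode
    rank_score: float

    @property
    def kind(self) -> str:
        return "node" if isinstance(self.member, str) else "supernode"

    @property
    def nodes(self) -> frozenset[str]:
        if isinstance(self.member, str):
            return frozenset([self.member])
        return self.member.base_nodes

    def sort_key(self) -> tuple[str, ...]:
        if isinstance(self.member, str):
            return (self.member,)
        return self.member.sort_key()


@dataclass
class UnifiedRanking:
    """The consensus output: ranked elements plus the node partition."""

    elements: list[RankedElement]
    unresolvable: set[str]
    unimportant: set[str]
    backbones: list[str] = field(default_factory=list)
    traces: list[DiscoveryTrace] = field(default_factory=list)
    unmerged_pairs: list[tuple[Supernode, Supernode]] = field(default_factory=list)

    @property
    def agreed_important(self) -> set[str]:
        return {e.member for e in self.elements if isinstance(e.member, str)}

    @property
    def supernodes(self) -> list[Supernode]:
        return [e.member for e in self.elements if isinstance(e.member, Supernode)]

    @property
    def supernode_members(self) -> set[str]:
        out: set[str] = set()
        for sn in self.supernodes:
            out |= sn.base_nodes
        return out


def universal_agreements(traces: list[DiscoveryTrace]) -> set[str]:
    """Nodes discovered by every backbone."""
    _check_traces(traces)
    agreed = traces[0].discovered_set
    for t in traces[1:]:
        agreed &= t.discovered_set
    return agreed


def _check_traces(traces: list[DiscoveryTrace]) -> None:
    if len(traces) < 2:
        raise ValueError("consensus requires at least 2 backbone traces")
    names = [t.backbone_name for t in traces]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate backbone names in traces: {names}")


def find_supernodes(
    g: SignedNetwork, traces: list[DiscoveryTrace], agreements: set[str]
) -> list[Supernode]:
    """Enumerate toss-up sets over the disagreement nodes.

    A subset of disagreement nodes qualifies when it is connected in
    ``g`` (topology at input time), its members' discovering-backbone
    sets are pairwise disjoint, and their union is the full backbone
    set.  Full-size all-singleton subsets ("triads" at k = 3) are
    enumerated first, then smaller subsets ("adjacencies"), each pass
    in lexicographic node order.  Overlapping supernodes may co-occur
    in the result; merging resolves them afterwards.
    """
    _check_traces(traces)
    backbone_set = frozenset(t.backbone_name for t in traces)
    k = len(backbone_set)
    label: dict[str, frozenset[str]] = {}
    for t in traces:
        for n in t.discovered:
            if n not in agreements:
                label[n] = label.get(n, frozenset()) | {t.backbone_name}
    disagreement = sorted(label)
    found: list[Supernode] = []
    for size in range(k, 1, -1):
        for combo in combinations(disagreement, size):
            covered: set[str] = set()
            ok = True
            for n in combo:
                lab = label[n]
                if covered & lab:
                    ok = False
                    break
                covered |= lab
            if not ok or covered != backbone_set:
                continue
            if not g.subgraph_is_connected(combo):
                continue
            found.append(
                Supernode.build([(frozenset([n]), label[n]) for n in combo])
            )
    return found


def _try_merge(a: Supernode, b: Supernode) -> Supernode | None:
    """Merge two supernodes by aligning positions on covered backbones.

    The merged positions are the cells of the common refinement of the
    two backbone partitions; each cell unions the two aligned
    positions.  Returns None when some intersecting pair of covered
    sets does not nest — the outcome of such a merge is undefined.
    """
    groups: list[tuple[frozenset[str], frozenset[str]]] = []
    for cov_a, pos_a in zip(a.covered, a.positions):
        for cov_b, pos_b in zip(b.covered, b.positions):
            cell = cov_a & cov_b
            if not cell:
                continue
            if not (cov_a <= cov_b or cov_b <= cov_a):
                return None
            groups.append((pos_a | pos_b, cell))
    return Supernode.build(groups)


def merge_supernodes(
    supernodes: list[Supernode],
    unmerged_report: list[tuple[Supernode, Supernode]] | None = None,
) -> list[Supernode]:
    """Repeatedly merge supernodes that share a base node.

    Pairs are examined in lexicographic order of their smallest base
    nodes; a merged supernode re-enters the pool and may merge again.
    Sharing pairs whose merge is undefined (non-nesting backbone
    partitions) are left unmerged and appended to ``unmerged_report``
    when provided.
    """
    pool = sorted(supernodes, key=Supernode.sort_key)
    flagged: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    while True:
        merged_any = False
        for i, j in combinations(range(len(pool)), 2):
            a, b = pool[i], pool[j]
            if not (a.base_nodes & b.base_nodes):
                continue
            key = (a.sort_key(), b.sort_key())
            if key in flagged:
                continue
            merged = _try_merge(a, b)
            if merged is None:
                flagged.add(key)
                if unmerged_report is not None:
                    unmerged_report.append((a, b))
                continue
            pool = [sn for idx, sn in enumerate(pool) if idx not in (i, j)]
            pool.append(merged)
            pool.sort(key=Supernode.sort_key)
            merged_any = True
            break
        if not merged_any:
            return pool


def _position_score(
    members: frozenset[str], covering: frozenset[str], rank: dict[str, dict[str, int]]
) -> float:
    """Mean over covering backbones of the earliest member rank."""
    per_backbone = []
    for b in sorted(covering):
        ranks = [rank[b][m] for m in members if m in rank[b]]
        if not ranks:
            raise KeyError(
                f"no member of position {sorted(members)} was discovered by backbone {b}"
            )
        per_backbone.append(min(ranks))
    return sum(per_backbone) / len(per_backbone)


def rank_elements(
    elements: list[str | Supernode],
    traces: list[DiscoveryTrace],
    unresolvable: set[str] | None = None,
    unimportant: set[str] | None = None,
) -> UnifiedRanking:
    """Score and order the consensus elements.

    A plain node (universal agreement) is scored by its mean discovery
    rank over all backbones.  A supernode is scored by the mean of its
    position scores; a position covering several backbones contributes
    the mean of its per-backbone ranks, and a multi-node position uses
    the rank of whichever member was discovered first under each
    covering backbone.  Lower scores rank earlier; ties break on the
    lexicographically smallest member.
    """
    _check_traces(traces)
    rank = {
        t.backbone_name: {n: r for r, n in enumerate(t.discovered, start=1)}
        for t in traces
    }
    scored: list[RankedElement] = []
    for el in elements:
        if isinstance(el, str):
            try:
                score = sum(rank[b][el] for b in rank) / len(rank)
            except KeyError:
                raise KeyError(
                    f"node {el!r} is not present in every backbone trace"
                ) from None
        else:
            pos_scores = [
                _position_score(members, covering, rank)
                for members, covering in zip(el.positions, el.covered)
            ]
            score = sum(pos_scores) / len(pos_scores)
        scored.append(RankedElement(member=el, rank_score=score))
    scored.sort(key=lambda e: (e.rank_score, e.sort_key()))
    return UnifiedRanking(
        elements=scored,
        unresolvable=set(unresolvable or ()),
        unimportant=set(unimportant or ()),
        backbones=sorted(rank),
        traces=list(traces),
    )


def consensus_ranking(
    g: SignedNetwork,
    backbones: tuple[str, ...] = ("BET", "CLO", "DEG"),
    zero_tol: float = DEFAULT_ZERO_TOL,
    path_method: str = "auto",
    progress=None,
) -> UnifiedRanking:
    """The full pipeline: iterate every backbone, then unify.

    Runs the iterative loop per backbone, extracts universal
    agreements, detects and merges supernodes over the disagreement
    nodes, flags the leftovers unresolvable, and returns the ranked
    consensus.  The agreed-important, supernode-member, unresolvable
    and unimportant classes partition the node set.
    """
    if len(backbones) < 2:
        raise ValueError("consensus requires at least 2 backbones")
    if len(set(backbones)) != len(backbones):
        raise ValueError(f"duplicate backbone names: {backbones}")
    traces = [
        iterate(g, b, zero_tol=zero_tol, path_method=path_method, progress=progress)
        for b in backbones
    ]
    agreements = universal_agreements(traces)
    discovered_any: set[str] = set()
    for t in traces:
        discovered_any |= t.discovered_set
    supernodes = merge_supernodes(
        find_supernodes(g, traces, agreements), unmerged_report=(unmerged := [])
    )
    members: set[str] = set()
    for sn in supernodes:
        members |= sn.base_nodes
    unresolvable = (discovered_any - agreements) - members
    unimportant = set(g.nodes) - discovered_any
    ranking = rank_elements(
        sorted(agreements) + supernodes, traces, unresolvable, unimportant
    )
    ranking.unmerged_pairs = unmerged
    return ranking


def expanded_rank_vector(
    r: UnifiedRanking | DiscoveryTrace, g: SignedNetwork
) -> dict[str, float]:
    """Per-node rank vector for cross-method correlation.

    Every node of an element inherits the element's 1-based position in
    the ranking; all remaining nodes (unimportant, unresolvable, or
    undiscovered for a single trace) share the tied last position,
    number-of-elements + 1.
    """
    vector: dict[str, float] = {}
    if isinstance(r, DiscoveryTrace):
        for pos, node in enumerate(r.discovered, start=1):
            vector[node] = float(pos)
        tied = float(len(r.discovered) + 1)
    else:
        for pos, el in enumerate(r.elements, start=1):
            for node in el.nodes:
                vector[node] = float(pos)
        tied = float(len(r.elements) + 1)
    for node in g.nodes:
        vector.setdefault(node, tied)
    return vector


def spearman(u: dict[str, float], v: dict[str, float]) -> float:
    """Spearman rank correlation of two keyed vectors (average-rank ties)."""
    if set(u) != set(v):
        raise ValueError("rank vectors are keyed by different node sets")
    if len(u) < 3:
        raise ValueError("need at least 3 nodes for a rank correlation")
    keys = sorted(u)
    rho = scipy.stats.spearmanr([u[k] for k in keys], [v[k] for k in keys]).statistic
    return float(rho)


def _serialize_supernode(sn: Supernode) -> str:
    """Pipe-separated positions, comma-separated members:
    ``B3,B4|C5,CD3,CD4|D2,CD3,CD4``."""
    return "|".join(",".join(sorted(pos)) for pos in sn.positions)


def write_ranking_tsv(r: UnifiedRanking, path: str) -> None:
    """Ranked elements as TSV (position, rank_score, element_type, members)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\trank_score\telement_type\tmembers\n")
        for pos, el in enumerate(r.elements, start=1):
            members = (
                el.member if isinstance(el.member, str) else _serialize_supernode(el.member)
            )
            fh.write(f"{pos}\t{el.rank_score!r}\t{el.kind}\t{members}\n")


def write_partition_json(r: UnifiedRanking, path: str) -> None:
    """Full consensus report: the four-way partition, supernode
    structure, per-backbone traces and any unmerged supernode pairs."""
    import json

    payload = {
        "backbones": r.backbones,
        "agreed_important": sorted(r.agreed_important),
        "supernodes": [
            {
                "positions": [sorted(pos) for pos in el.member.positions],
                "covered_backbones": [sorted(cov) for cov in el.member.covered],
                "rank_score": el.rank_score,
            }
            for el in r.elements
            if isinstance(el.member, Supernode)
        ],
        "unresolvable": sorted(r.unresolvable),
        "unimportant": sorted(r.unimportant),
        "elements": [
            {
                "position": pos,
                "rank_score": el.rank_score,
                "type": el.kind,
                "members": sorted(el.nodes),
            }
            for pos, el in enumerate(r.elements, start=1)
        ],
        "traces": {t.backbone_name: list(t.discovered) for t in r.traces},
        "unmerged_pairs": [
            [a.describe(), b.describe()] for a, b in r.unmerged_pairs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
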