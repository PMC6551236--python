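# Methods

## Scope and model

`unicent` operates on undirected networks whose edge weights lie in
[−1, 1] \ {0}; a positive weight is a supportive association, a negative one
antagonistic. Zero weights are rejected at parse time: every formula in the
method treats a zero-weight edge identically to an absent edge, so admitting
them would only create two spellings of the same network. Node identifiers
are opaque strings; their lexicographic order is the single tie-breaking
order used everywhere, which makes every stage of the pipeline fully
deterministic — re-running any computation on the same input yields
bit-identical output.

## Signed path labels

The pairwise primitives are the gain G(i, j) — the maximum edge-weight
product over *simple* paths from i to j with positive product — and the loss
L(i, j), the most negative product; both are 0 when no qualifying path
exists. Simple paths are the only finite reading of "all paths": when every
|w| < 1 a cycle strictly shrinks magnitude and can never help, and edges with
|w| = 1 would otherwise admit endless zero-cost circling.

Two search strategies sit behind one interface:

- **exact** (default up to 30 nodes): a best-first label search keeping, per
  (node, sign-parity) state, a Pareto frontier of (magnitude, visited-set)
  labels. A label is pruned only when another label at the same state has
  magnitude at least as large and a visited set contained in the candidate's;
  any simple extension of the pruned label is then matched or beaten by the
  same extension of the pruner, so the first pop of each state is its true
  optimum. The search stops once every state reachable in the sign-lift graph
  is settled, and labels that provably cannot beat any still-unsettled
  state — their magnitude times the unconstrained max-product walk bound
  falls below that state's best-known value — are discarded. The frontier
  can still grow combinatorially on dense networks, hence the size cutoff.
- **fast** (default above 30 nodes): the classic signed Dijkstra variant
  keeping a single settled label per (node, sign), relaxing both signs
  through every edge and refusing to revisit a node on the label's own path.
  Near-linear-time, but not exact: when every best route to an intermediate
  node already passes through the target, the alternative that avoids it has
  been discarded. (A five-node network with weights 0.9, 0.9, −0.9 on one
  branch and 0.6, −0.6 on another exhibits the miss.) Its labels are always
  realizable paths, so it only ever under-estimates magnitudes.

The 30-node threshold was chosen from the measured growth of the exact
frontier on the synthetic ensembles this package targets (sub-second per
all-pairs call below it, occasionally minutes above); both modes are
selectable explicitly wherever labels are computed. Co-optimal paths are
resolved deterministically: fewer edges first, then the lexicographically
smallest node sequence. That canonical witness matters because signed
betweenness counts witness membership.

An exponential brute-force enumerator over all simple paths (≤ 10 nodes)
serves as the independent oracle; the exact search is tested against it
pair-for-pair, including witness identity.

## Backbones

Signed closeness sums G + L towards every other node and takes the absolute
value; signed degree does the same with incident edge weights; signed
betweenness counts, over all unordered pairs, the recorded positive and
negative witness paths on which a node is interior. Three conventions the
index definitions leave open are fixed as follows: each unordered pair
contributes at most one positive and one negative path (the canonical
witness), endpoints are not "on" a path, and pairs are counted once rather
than twice — the last being a uniform factor that cannot affect any ranking.
All three indices are non-negative by construction. The registry accepts any
further `network -> CentralityVector` function under a fresh name, so runs
may combine arbitrary k ≥ 2 algorithms.

## Iteration

The loop computes the backbone on the current network, extracts the arg-max
node (ties: lexicographic), removes it together with every stable-triad edge
through it — a triangle with zero or exactly two negative edges, the
structurally balanced configurations in which two nodes associate through a
mutual friend or enemy — and recomputes from scratch, stopping when the
maximum centrality falls to the zero tolerance. The tolerance defaults to
1e−9 because closeness values are sums of floating products that rarely reach
exact zero. Stable triads are evaluated on the *current* (already reduced)
network, and all-pairs labels are recomputed every iteration; no incremental
shortcut is attempted. A most-central node with no stable triads still has
itself (and its incident edges) removed. The path-search mode is resolved
once per run from the initial network size, so one trace is produced by one
algorithm throughout. Each iteration removes exactly one node, bounding the
loop at n iterations.

## Consensus

Universal agreements (nodes in every trace) enter the ranked set directly.
Over the remaining disagreement nodes, supernodes are enumerated full-size
first (all-singleton discoverer sets), then smaller, lexicographically within
each pass; a qualifying subset must be connected *in the original network* —
by the time supernodes form, the backbones have already consumed the edge
weights, so input-time topology is the relevant notion of adjacency.
Formation happens after all traces complete rather than on the fly: an
early-forming rule would still leave indirect-effect disagreements
unresolved, so the simpler batch rule is preferred.

Merging aligns two overlapping supernodes position-by-position on the
backbones each position covers (the common refinement of the two backbone
partitions) and unions aligned positions. This single rule reproduces the
triad+adjacency merge, both triad-triad overlap patterns, the
adjacency-adjacency overlap, and their chained compositions, for any k. When
two intersecting covered sets fail to nest the refinement would split a
position, and no defined outcome exists; such pairs are left unmerged and
reported rather than guessed (at k = 3 they cannot arise, since a node's
discoverer set is fixed). Pairs are merged in lexicographic order of smallest
base node until no two supernodes share a node. A merged supernode may
legitimately repeat a base node across *positions* (an alternative node can
stand in for two different backbones); disjointness is guaranteed *between*
supernodes.

One disagreement pattern is deliberately left out: when one backbone finds
two nodes important and the other backbones split them, the pair is not a
toss-up, and it is reported unresolvable rather than encapsulated as a new
element type.

Ranking uses unweighted means of discovery ranks: agreements average over all
backbones; a supernode averages its position scores, each position scored
under its covering backbones with a multi-node position represented by its
earliest-discovered member. Weighted averaging is a known possible
refinement and is not implemented.

Expanded rank vectors give every member of an element that element's
position and assign all unimportant and unresolvable nodes the tied last
position (element count + 1); tied-last is order-isomorphic to "zero
centrality" for rank correlation. Correlations are Spearman with
average-rank tie handling (`scipy.stats.spearmanr`).

## Synthetic networks

The modular generator emulates a mid-sized microbial co-occurrence network:
126 nodes and 5 modules by default (module membership round-robin), dense
intra-module edges (p_in = 0.4) that are mostly supportive (15% negative),
sparse inter-module edges (p_out = 0.03, half negative), weight magnitudes
uniform on [0.2, 0.9], and one planted hub per module wired to all module
members with strong positive weights ([0.75, 0.95]). The scale-free
generator samples a preferential-attachment skeleton (2 edges per new node)
and signs weights independently (30% negative) — the conventional reading of
a "scale-free synthetic" benchmark. Both are byte-for-byte deterministic
under (spec, seed).

What the generator does *not* emulate: compositionality artefacts of real
co-occurrence inference, weight distributions estimated from finite counts,
hub overlap between modules, or degree-correlated sign patterns. Passing
tests on these inputs therefore demonstrates the algorithmic contracts —
exactness, determinism, partition completeness, consensus direction — not
biological validity on any particular real dataset.

Golden fixtures (`triad_tossup`, `adjacency_tossup`) are small networks found
by randomized search and then *verified by an independent re-simulation* of
the loop over exhaustively enumerated paths; the test suite re-runs that
verification rather than trusting the stored annotation. The `merge_chain`
fixture is symbolic: its traces are part of the fixture, exercising the
chained triad/adjacency merge in isolation.

## Problem sizes and numerical choices

The test and reproduction ensembles use networks of 5–60 nodes: exhaustive
oracle comparisons at ≤ 8 nodes, iterative-loop contracts at ≤ 40, partition
checks on 24–30-node modular and scale-free networks, and consensus-direction
runs on 60-node, 5-module networks with planted hubs — sizes at which the
whole pipeline, including per-iteration all-pairs recomputation, stays
comfortably interactive. Magnitude ties use a 1e−9 relative tolerance;
the iteration zero-tolerance is 1e−9; weight validation is exact.

## Known limitations

- The fast path search is an approximation (documented miss pattern above);
  exactness guarantees apply to the exact mode only.
- Betweenness multiplicity over co-optimal paths is resolved by one canonical
  witness per (pair, sign); an index counting *all* co-optimal paths would
  differ on networks with many exact ties.
- Merge semantics for non-nesting backbone partitions (possible at k > 3) are
  undefined and reported, not resolved.
- Directed networks, multigraphs, edge metadata beyond one signed weight, and
  eigenvector-style backbones (which can be plugged in externally but are not
  shipped) are out of scope.
- Iteration recomputes all-pairs labels every round; cost grows steeply with
  network size, and networks beyond the low hundreds of nodes are slow in
  this pure-Python implementation.
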