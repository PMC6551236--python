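# unicent — unified consensus centrality for signed biological networks

`unicent` finds the most central nodes in **signed, weighted, undirected
networks** — microbial co-occurrence networks, gene co-expression networks and
similar association graphs whose edge weights lie in [−1, 1], with negative
weights encoding antagonism (co-exclusion, anti-correlation). In such networks
no single notion of "importance" is privileged: betweenness, closeness and
degree routinely disagree, each with its own spatial bias (one favours
articulation paths, one the geometric middle, one the densest component).
`unicent` runs *k* ≥ 2 centrality algorithms in an iterative, bias-removing
form and then unifies their residual disagreements into a single ranked set of
nodes and **supernodes** (explicit centrality toss-ups), instead of forcing a
winner. It is intended for systems-biology practitioners who need one
defensible central-node list from a correlation network.

## The method

**Signed path labels.** For nodes *i*, *j*, the *gain* G(*i*, *j*) is the
maximum product of edge weights over simple paths with positive product, and
the *loss* L(*i*, *j*) the most negative product. Because |w| ≤ 1, every
extra hop shrinks a product's magnitude, so G and L measure the strongest
supportive and antagonistic association each pair can route.

**Three signed backbones.**

- closeness: Centrality_CLO(*i*) = | Σ_{j≠i} G(*i*, *j*) + L(*i*, *j*) |
- degree: Centrality_DEG(*i*) = | Σ_{j≠i} W(*i*, *j*) | over incident edges
- betweenness: Centrality_BET(*i*) = Σ_{pairs {j,k}} γ_jk(*i*) + λ_jk(*i*),
  counting the recorded maximum positive and negative paths on which *i* is
  interior.

Any other index can be registered by name and slotted in.

**Iteration.** Each backbone runs in a loop: compute centralities, extract the
arg-max node *m*, remove *m* and every *stable-triad* edge through *m* (a
triangle with zero or exactly two negative edges — structural balance says its
end nodes associate *because of* *m*), recompute, stop when everything is
numerically zero. Discovery order is the backbone's de-biased ranking.

**Consensus.** Nodes discovered by all backbones are *universal agreements*.
Among the rest, a **supernode** is a connected set of 2..k nodes whose
discovering-backbone sets are disjoint and cover all backbones — iteration
makes such sets genuine toss-ups. Supernodes sharing members are merged by
aligning positions on the backbones they cover; leftovers are flagged
*unresolvable*; nodes no backbone found are *unimportant*. Elements are scored
by mean discovery rank and sorted. The four classes partition the node set.

## Worked example

```bash
python examples/03_consensus_ranking.py
```

```
network: 60 nodes, 227 edges

ranked consensus elements (lower score = more central):
   1. score  3.00  node      n01
   2. score  6.33  node      n00
   3. score  6.50  supernode [{n02,n03,n15}, {n05,n08,n13,n30,n43,n47,n51,n53,n57}]
   4. score  8.25  supernode [n06, n49]
   ...

coverage: 12 agreed important, 23 in supernodes, 13 unresolvable, 12 agreed unimportant (= 60 nodes)
universal agreement: 40%   resolvable: 78%
```

The network is a synthetic 5-module signed co-occurrence network with one
planted hub per module. `n01` and `n00` are hubs every backbone agrees on;
element 3 is a supernode — the backbones split over which of its members is
the real centre, so the set is reported as one ranked toss-up rather than an
arbitrary pick. The coverage line is the four-way partition; "resolvable"
is the fraction of nodes whose status the consensus could settle.
`examples/04_rank_correlations.py` then shows the unified ranking correlating
positively with *every* backbone at once (Spearman +0.23 to +0.48 here),
which no single backbone achieves against the other two.

The same pipeline is available from the shell:

```bash
unicent generate --topology modular --n 126 --modules 5 --seed 7 --out net.tsv
unicent run --input net.tsv --backbones BET,CLO,DEG --out results/run
unicent correlate --inputs results/run.trace.BET.tsv,results/run.trace.CLO.tsv \
    --network net.tsv --out results/corr.tsv
```

`run` writes `<prefix>.ranking.tsv`, `<prefix>.partition.json` and one
`<prefix>.trace.<backbone>.tsv` per backbone.

## Layout

- `src/unicent/graph.py` — signed network container, edge-list/GML I/O
- `src/unicent/paths.py` — signed max-product path labels (exact and fast search)
- `src/unicent/backbones.py` — signed closeness/degree/betweenness + registry
- `src/unicent/iteration.py` — stable triads and the iterative loop
- `src/unicent/consensus.py` — agreements, supernodes, merging, ranking, Spearman
- `src/unicent/synthetic.py` — seeded modular / scale-free generators, fixtures
- `src/unicent/cli.py` — the `unicent` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
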