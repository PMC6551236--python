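"""Gains and losses: signed max-product path labels on a toy network.

Builds a five-node signed network and prints, for a few node pairs, the
best positive edge-weight product G (the "gain" the pair can exchange),
the most negative product L (the "loss"), and the paths realising them.
"""

from unicent import SignedNetwork, all_pairs_labels

g = SignedNetwork(
    [
        ("a", "b", 0.9),
        ("b", "c", 0.8),
        ("a", "c", 0.5),
        ("c", "d", -0.6),
        ("d", "e", 0.7),
    ]
)
labels = all_pairs_labels(g)

for pair in [("a", "c"), ("a", "d"), ("a", "e"), ("b", "e")]:
    i, j = pair
    print(
        f"{i}-{j}:  G = {labels.gain(i, j):+.4f} via {'-'.join(labels.pos_witness(i, j)) or '(none)'}"
        f"   L = {labels.loss(i, j):+.4f} via {'-'.join(labels.neg_witness(i, j)) or '(none)'}"
    )

# a-c shows a two-hop product (0.9 * 0.8 = 0.72) beating the direct 0.5
# edge; pairs past the negative c-d edge have no positive path at all,
# only a loss whose magnitude shrinks with every extra hop.
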