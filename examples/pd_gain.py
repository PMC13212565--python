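"""Phylogenetic diversity gain from newly added genomes.

First the hand-checkable toy tree ((A:0.1,B:0.2):0.3,C:0.4);, then a
simulated pure-birth tree where one lineage's tips are 'new' genomes added
to a reference set. PD is the branch-length sum of the spanning subtree;
the gain is the extra branch length the new genomes contribute, reported
as percent growth over the reference PD.
"""

import dendropy
import numpy as np

from limnoscope.phylo import pd, pd_gain
from limnoscope.synthetic import gen_tree

toy = dendropy.Tree.get(
    data="((A:0.1,B:0.2):0.3,C:0.4);", schema="newick",
    preserve_underscores=True,
)
print(f"toy tree PD(A,B,C) = {pd(toy, ['A', 'B', 'C']):.1f}")
print(f"toy tree PD(A,B)   = {pd(toy, ['A', 'B']):.1f}")
gain, pct = pd_gain(toy, ["A", "B"], ["C"])
print(f"adding C to (A,B): gain = {gain:.1f}, +{pct:.1f} %")

rng = np.random.default_rng(1)
tree = gen_tree({"reference": 12, "novel": 6}, 2.0, rng)
reference = [f"reference_g{i:03d}" for i in range(12)]
novel = [f"novel_g{i:03d}" for i in range(6)]
gain, pct = pd_gain(tree, reference, novel)
print(
    f"\nsimulated tree: 6 new genomes expand the 12-genome reference PD "
    f"by {gain:.3f} substitutions/site (+{pct:.2f} %)"
)
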