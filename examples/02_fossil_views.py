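"""Fossil sampling and the two observable views of a complete tree.

Drops Poisson(psi = 0.1) fossil occurrences on a simulated tree, then
derives the extant (ultrametric) view and the FBD view in which the last
fossil of an unsampled extinct lineage becomes a fossil tip and all other
fossils become sampled ancestors.
"""

from collections import Counter

import numpy as np

import fossilbisse as fb

rng = np.random.default_rng(2)
tree = fb.simulate_complete_tree(fb.SCENARIOS["S1"].parameters(), 100, rng)
occurrences = fb.sample_fossils(tree, psi=0.1, rng=rng)

extant = fb.prune_to_extant(tree)
fbd = fb.build_fbd_tree(tree, occurrences)

print(f"fossil occurrences: {len(occurrences)} "
      f"(expected ~ psi x total length = {0.1 * tree.total_branch_length():.0f})")
print(f"extant view: {len(extant.tips())} tips, ultrametric={extant.is_ultrametric()}")
kinds = Counter(n.kind for n in fbd.samples())
print(f"FBD view samples: {dict(kinds)}")
print("fossil tips + sampled ancestors == occurrences:",
      kinds["fossil_tip"] + kinds["sampled_ancestor"] == len(occurrences))

# Every occurrence becomes exactly one node; most occurrences are sampled
# ancestors because extant lineages (all sampled at rho = 1) dominate the
# tree near the present.
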