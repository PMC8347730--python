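"""Reduce a redundant family to a diverse set of representatives.

Pairwise k-mer dissimilarities are sorted; visiting pairs from the most
similar upward, the member closer to the rest of the set is deleted until
the target size remains — redundancy goes, outliers stay.
"""

import crossmotif as cm

fam = cm.simulate_families(cm.SimConfig(
    n_families=1, seqs_per_family=200, ancestor_length=250,
    substitution_rate=0.25, indel_rate=0.02, seed=7,
))[0]

dm = cm.distance_matrix(fam, k=3)
res = cm.reduce(dm, 40)
kept = cm.subset_family(fam, res.kept)

print(f"reduced {len(fam)} -> {len(kept)} representatives")
print("first removals (removed, kept partner, distance):")
for rid, pid, d in res.removed[:5]:
    print(f"  {rid} (partner {pid}, d={d:.3f})")

import numpy as np
idx = [dm.index(i) for i in res.kept]
sub = dm.data[np.ix_(idx, idx)]
tri = np.triu_indices(len(idx), 1)
print(f"min pairwise distance: full set {dm.data[np.triu_indices(len(dm),1)].min():.3f}"
      f" -> kept set {sub[tri].min():.3f}")
# The minimum pairwise distance can only rise: the closest pairs are
# exactly what the reduction dissolves.
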