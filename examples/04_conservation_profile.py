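"""Per-column conservation and a degenerate consensus pattern.

Shannon entropy in base 20 scores each alignment column between 0 (fully
conserved) and 1 (uniform over the 20 amino acids); a planted motif shows
up as a trough. The consensus extractor then summarises a column span as
fixed letters, bracket classes and X wildcards.
"""

import numpy as np

import crossmotif as cm
from crossmotif.conserve import profile, consensus_pattern, map_reference_span

plant = cm.MotifPlant("MKTAYIAKQRQISFV", [0], occupancy=1.0, anchored=True)
fam = cm.simulate_families(cm.SimConfig(
    n_families=1, seqs_per_family=30, ancestor_length=150,
    substitution_rate=0.35, indel_rate=0.0, planted_motifs=[plant], seed=8,
))[0]

aln = cm.progressive_align(fam)
prof = profile(aln, reference_id=fam[0].id)

start = fam[0].truth[0].start
cols = map_reference_span(aln, fam[0].id, start, start + 14)
motif_s = float(np.nanmean(prof.entropy[cols]))
flank_s = float(np.nanmean(np.delete(prof.entropy, cols)))
print(f"mean entropy: motif columns {motif_s:.3f} vs flanks {flank_s:.3f}")
# The planted columns are (nearly) invariant, the mutated flanks are not.

pattern = consensus_pattern(prof, cols, t_fix=0.7, t_class=0.8)
print("consensus over the motif span:", pattern.pattern)
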