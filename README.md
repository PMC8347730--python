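# crossmotif

Do unrelated protein families share a short sequence motif? `crossmotif`
is a library for answering that question end to end on protein sequence
sets: it reduces large, redundant families to diverse representatives,
builds neighbor-joining trees and progressive multiple alignments,
profiles per-column conservation, discovers motifs by expectation
maximization, and decides — with controls — whether any motif is shared
across families. It was built for the setting where several candidate
receptor families for one ligand (here, the neural glycan HNK-1, whose
proposed protein receptors are the laminins, cadherin-2 and HMGB-1/2)
are screened for a common sequence signature, but every stage is generic.

Because real receptor-family harvests are large, noisy downloads, the
package ships a synthetic family simulator: families diverge from
independent random ancestors by substitutions and indels, and degenerate
motifs can be planted at chosen occupancy and degradation with ground
truth recorded. Every claim the pipeline makes is therefore testable as
a positive or negative control without touching a database.

## The methods in brief

- **Reduction.** Pairwise dissimilarity between unaligned sequences is a
  k-mer set overlap, `d = 1 − |Ka ∩ Kb| / min(|Ka|, |Kb|)`. All pairs
  are sorted by distance; visiting pairs from the most similar upward,
  the member closer to the rest of the surviving set is deleted until
  `k` representatives remain — redundancy dissolves, outliers stay.
- **Trees and alignment.** Saitou–Nei neighbor joining (exact on
  additive matrices) supplies both the tree of the merged set and the
  guide tree for a progressive profile aligner (BLOSUM62, affine gaps,
  gap open −11 / extend −1, profile columns scored as the expected
  pairwise substitution score).
- **Conservation.** Column variability is Shannon entropy in base 20,
  `S = −Σ_a p_a log₂₀ p_a ∈ [0, 1]` over the residues of the column
  (gaps excluded, reported separately); a column span can be summarised
  as a degenerate consensus such as
  `RXX[VL]XX[KR][KR]YXGC[LI][KR]X[LI]EISR[TS]`.
- **Motif discovery.** A ZOOPS (zero-or-one occurrence per sequence)
  mixture model fitted by EM: each sequence carries a width-W motif
  drawn from a position probability matrix with prior γ, or is pure
  background. Repeated discovery masks each reported motif before the
  next search. Significance is an empirical permutation E-value from
  re-fitting the same search on within-sequence residue shuffles.
- **The cross-family verdict.** A motif counts as shared only if it is
  significant (E ≤ α) *and* covers at least `c_min` of every family
  under three leakage guards (leave-one-family-out PPM re-estimation, a
  train/validation family split, and a shuffle-calibrated score
  threshold with a match-quality floor) — see `docs/methods.md` for why
  each is needed.

## Worked example

```python
import crossmotif as cm

plant = cm.MotifPlant("MKTAYIAKQRQISFV", target_families=[0, 1, 2],
                      occupancy=0.9, degradation=0.1)
fams = cm.simulate_families(cm.SimConfig(
    n_families=3, seqs_per_family=30, ancestor_length=150,
    substitution_rate=0.3, indel_rate=0.0, planted_motifs=[plant], seed=61))
verdicts = cm.shared_motif_search(fams, n_motifs=2, n_perms=99, seed=1,
                                  include_pairs=False, refine=False)
for v in verdicts:
    print(f"rank {v.motif.rank} {v.motif.consensus}: min coverage "
          f"{min(v.coverage.values()):.2f}, E={v.e_value:.3g}, shared={v.shared}")
```

prints

```
rank 1 MKTAYIAKQRQISFV: min coverage 0.90, E=0.01, shared=True
rank 2 KFVCWREYNDM: min coverage 0.00, E=inf, shared=False
```

Rank 1 recovers the planted 15-mer exactly: it covers 90% of every
family (matching the planted occupancy) and its log-likelihood ratio
beat all 99 shuffle-null fits, so E = 1/100 — the smallest value 99
permutations can certify. Rank 2 is the best remaining motif after
masking; it belongs to no family but its discovery set, covers nothing
under the leave-one-family-out scan, and is therefore not shared. On
three families with no plant, both ranks come out `shared=False` — the
negative control.

The `examples/` directory has one short script per capability
(simulation, reduction, trees/alignment, conservation, motif discovery,
cross-family search); each prints the numbers it computes and a line on
what they mean. A thin CLI (`crossmotif simulate|reduce|nearest|tree|
align|conserve|motifs|run`) wraps the same calls for shell use.

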