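# Methods

This note documents the models and procedures implemented in
`crossmotif`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data controls do
and do not establish.

## Synthetic families (`famsim`)

Each family descends from its own ancestor, a uniform random string over
the 20 canonical amino acids, so distinct families are statistically
unrelated. Each member sequence applies to the ancestor:

- **substitutions** — per-site Bernoulli with rate `substitution_rate`
  (default 0.3 per site; at this rate two family members share roughly
  half their residues, enough divergence to exercise every downstream
  stage while keeping families alignable), replacement uniform over the
  19 alternatives;
- **indels** — a Binomial(L, `indel_rate`) number of events (default
  0.02/site), insertion or deletion with equal probability, lengths
  geometric with mean `indel_length_mean` (default 2) capped at 10,
  inserted residues uniform.

Motif plants are degenerate patterns (fixed letters, bracket classes,
`X`). Occupancy is realised as the exact count `round(occupancy · n)` of
carrier sequences rather than per-sequence Bernoulli, so recovery
statistics have a fixed denominator and control tests are non-flaky.
Each instantiated copy draws class/wildcard positions at random, then
degrades each position to a uniform residue with probability
`degradation`; the degraded offsets are recorded in the ground truth, so
tests can assert pattern identity at every non-degraded position.
Copies are *inserted* (never overwritten) at least one residue from the
ends, and never inside a previously planted copy. Two placement modes
exist: the default draws an independent uniform position per sequence
(appropriate for discovery benchmarks, where position carries no
signal); `anchored=True` draws one relative position per family, so all
instances sit at homologous coordinates and an aligner can stack them
into common columns — the mode used by alignment and conservation
controls. Randomness comes from one global seed with per-family
substreams keyed on (seed, family index), so adding a family never
changes earlier families.

What the generator does **not** emulate: tree-structured within-family
divergence (all members are siblings of the ancestor), rate
heterogeneity across sites, empirical residue exchangeabilities, and
realistic length/domain architecture. Passing controls therefore show
that the pipeline behaves correctly under idealised homology and known
truth; they do not certify performance on real harvests, where deeper
divergence structure and compositional bias make every stage harder.

## Distances and reduction (`seqreduce`)

The dissimilarity between unaligned sequences is
`d = 1 − |Ka ∩ Kb| / min(|Ka|, |Kb|)` over sets of distinct k-mers
(k = 3 by default: with a 20-letter alphabet, 3-mers are informative at
family scale, and the matrix is computed as one sparse
sequence-by-k-mer product, seconds for thousands of sequences). This is
a fast alignment-free stand-in for alignment-derived distances; an
alignment-based fractional-identity distance is available once an
alignment exists.

Reduction visits all pairs in ascending (distance, id, id) order; from
each pair with both members alive it removes the member with the
smaller total distance to the surviving set — the more central one —
keeping outliers and hence the evenest spread. Ties remove the
lexicographically smaller id. The greedy rule is not provably optimal;
on small random instances it reaches at least 0.8 of the brute-force
max-min-distance optimum (property-tested), and on line metrics it is
exact. Nearest-to-reference selection sorts by (distance to reference,
id) and keeps the first n, reference included.

## Trees and progressive alignment (`msa`)

Neighbor joining follows Saitou–Nei with the Q-criterion; the Q matrix
is computed with grouped row sums so it is bit-symmetric, and ties are
broken by the lexicographically smallest pair of cluster representatives,
making the tree deterministic. Negative branch lengths are clamped to
zero. On additive matrices the reconstruction is exact (verified on 100
random 5–8 leaf trees against path-length matrices, and cross-checked
against scikit-bio's implementation).

The aligner merges profiles in post-order along a midpoint-rooted NJ
guide tree built from k-mer distances. Profiles are per-column frequency
vectors over 21 symbols (20 residues + gap); the profile–profile column
score is the expected BLOSUM62 substitution score, with gap frequency
contributing zero. The inner recurrence is a Gotoh affine-gap dynamic
programme (gap open −11, extend −1; a run of L gaps costs
`open + (L−1)·extend`) over the precomputed column-score matrix,
numba-compiled because the three DP states are mutually dependent within
a row and do not vectorise. For two sequences this reduces exactly to
pairwise affine-gap alignment and is score-identical to an independent
implementation (tested against Biopython's `PairwiseAligner`). No
iterative refinement is attempted; sets beyond a few thousand rows are
out of intended scope (the 15,000-sequence merge is exercised for
counting and tree work on reduced subsets, not full alignment).

## Conservation and consensus (`conserve`)

Column variability is Shannon entropy in base 20,
`S = −Σ_a p_a log₂₀ p_a`, which is 0 for a single residue type and 1
for the uniform distribution over 20 types. `p_a` is estimated over the
residues of the column only: gaps are excluded and reported as a
separate gap fraction, ambiguity codes (B/Z/X/U/J/O) are excluded from
the counts, all-gap columns carry an undefined flag rather than a
number, and columns with under 20% residue occupancy are flagged
low-coverage in tabular output. Coordinates are 1-based inclusive
throughout (a span a..b has b − a + 1 residues); reference masking keeps
exactly the columns where a chosen row has residues, and span mapping
returns the alignment columns of an ungapped-reference interval.

The consensus extractor formalises degenerate patterns with two
thresholds: a column with top-residue frequency ≥ `t_fix` (default 0.7)
becomes a fixed letter; otherwise, if the top 2–3 residues jointly reach
`t_class` (default 0.8) they become a bracket class ordered by
descending frequency (alphabetical on exact ties — the only
deterministic, row-order-invariant rule); otherwise `X`. Whether any
published consensus was produced by thresholds or by eye is generally
unknowable; these defaults reproduce typical published patterns on
alignments realising the stated frequencies and are fully configurable.

## Motif discovery (`motifdisc`)

The model is ZOOPS: a sequence of length L contains, with prior
probability γ, exactly one occurrence of a width-W motif at a uniformly
chosen admissible start, emitted column-wise from a position probability
matrix (PPM); otherwise the whole sequence is 0-order background.
Within-sequence repeats (e.g. a domain repeated five times in one
protein) are deliberately left to the separate scan step, which reports
every window whose log-odds score (bits) clears a threshold.

EM details that matter:

- **Initialisation.** Candidate seed words are substrings ranked by the
  total corpus count of their 3-mers (a cheap proxy for cross-sequence
  enrichment), taken at stride W/2 so any planted instance overlaps a
  candidate by at least half its width; the top `n_seeds` (default 20)
  each get 5 EM iterations and the best continues to convergence. The
  procedure is deterministic for a given input.
- **Numerics.** Pseudocount 0.01 per PPM cell; γ clipped to
  (10⁻⁶, 1−10⁻⁶); per-sequence posteriors computed in log space. The
  monotone quantity is the *penalized* objective (log-likelihood ratio
  plus the Dirichlet pseudocount log-prior), which MAP-EM guarantees
  non-decreasing; the trace is recorded on every fit and asserted in
  tests with 10⁻⁸ slack.
- **Masking.** Reported occurrences (posterior ≥ 0.5) are overwritten
  with a neutral symbol excluded from both candidate windows and
  background re-estimation before the next motif rank is searched, so
  later motifs cannot overlap earlier ones.
- **Width selection.** `discover` fits the coarse grid
  {6, 8, 11, 15, 21, 30} clipped to [w_min, w_max], picks the width
  maximising log-likelihood ratio per column, and refines ±2 (the
  refinement can be disabled for calibration-scale runs). Selecting by
  permutation E-value per width is available but costs B EM fits per
  width per rank; it is off by default.
- **Significance.** The E-value is empirical:
  `E = n_tested · (1 + #{null llr ≥ observed llr}) / (B + 1)` over B
  within-sequence residue shuffles, each re-fitted with the same
  single-width EM search. `n_tested` defaults to 1 (the E-value of the
  one reported motif); with B = 99 the smallest certifiable value is
  0.01. Analytic motif E-values of the MEME kind (which can reach
  astronomically small magnitudes on large real families) are out of
  scope by construction; permutation E-values are this package's only
  significance currency, with a floor set by B.

## The shared-motif verdict (`crossfam`)

A motif discovered on a pooled set counts as **shared** when its
permutation E-value is ≤ α (default 0.01) *and* its coverage reaches
`c_min` (default 0.25) in every participating family. Coverage is where
all the difficulty lives: three distinct leakage mechanisms each produce
confident false "shared" calls on pooled unrelated families, and the
implementation stacks one guard per mechanism.

1. **Family-mixture motifs.** EM on a pooled set of internally
   homologous but mutually unrelated families happily fits a PPM that is
   a blend of one ancestral window per family; every family then
   "contains" the motif. Guard: coverage of family f is computed with a
   PPM re-estimated from the motif's occurrence windows in the *other*
   families (leave-one-family-out); a mixture collapses because the
   leave-out PPM no longer contains f's component, while a genuinely
   shared motif survives.
2. **Diffuse PPMs.** A near-background PPM scores some window of any
   sequence above any fixed threshold. Guard: the score threshold is
   calibrated per family against within-sequence residue shuffles — a
   sequence counts as covered only above the 0.95 quantile of shuffled
   best-window scores, so a diffuse PPM covers ~5% of any family.
3. **Chance ancestor resemblances.** Among thousands of candidate
   window pairings, EM finds the one pair of unrelated-ancestor windows
   that happen to resemble each other; because the resemblance is
   ancestral, *every* sequence of each family inherits it, so neither
   held-out sequences nor shuffle nulls expose it. Guards: discovery
   runs on one half of each family with coverage measured on the
   held-out half, and — decisive for this mechanism — a covered window
   must also reach half of the PPM's maximum attainable log-odds. A
   degraded true instance (occupancy 0.9, degradation 0.1) scores ~80%
   of the maximum; chance resemblances between unrelated ancestors sit
   far below half.

The permutation E-value is computed lazily, only for motifs whose
coverage already passes `c_min` (a coverage failure decides "not shared"
without the expensive null; such motifs report E = +inf). Calibration,
re-measured by the acceptance suite on 20 seeded replicates each way:
zero negative-control runs with any shared verdict (pooled and all
pairwise searches), and 20/20 positive-control detections.

Motif-set comparison scores every cross-family pair of consensus
strings by global alignment with free end gaps (BLOSUM62, open −11 /
extend −1, via Biopython's `PairwiseAligner`) and reports the top 10; a
PPM-correlation mode exists as a secondary comparison. No automated
"biologically meaningful" call is made on weak similarities — the table
is the output.

## Problem sizes

Defaults mirror the study design this pipeline re-implements: 400
representatives per family for motif work, thousands for merge/tree
work, 30 motifs per family, top-10 comparisons, motif widths 6–30. The
test and acceptance suites run the full-size set constructions (2,000 →
400; 3 × 5,200 → 3 × 5,000 → 15,000 merge; 1,000 → 700 nearest) but
exercise EM-heavy calibration at 3 × 30 sequences × 150 residues and
recovery power at 100 × 300, sizes chosen so the complete battery runs
on one CPU in minutes while leaving the measured error rates their
stated headroom.

## Known limitations

- The aligner is strictly progressive; early guide-tree errors are
  frozen in, and alignment quality at k-mer-distance saturation (very
  deep divergence) degrades.
- Permutation E-values have a resolution floor of `n_tested/(B+1)` and
  inherit the cost of B EM fits; they are not comparable in magnitude
  to analytic E-values.
- The verdict calibration is established under the simulator's
  conditions (uniform ancestors, sibling divergence); compositionally
  biased real families may need a stricter `null_quantile` or
  `match_fraction`.
- `reduce` recomputes nothing when the sorted pair list is exhausted
  early, because with a full pair list exhaustion cannot occur before
  the target size is reached; partial distance matrices are unsupported.
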