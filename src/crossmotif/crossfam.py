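"""Cross-family motif questions and pipeline orchestration.

Given several protein families, the questions are: (i) does any motif
recur across all families (pooled search) or across any pair of families
(pairwise searches), and (ii) how similar are the independently
discovered per-family motifs to each other (sliding comparison of
consensus strings by global alignment with free end gaps)?

A motif counts as *shared* only if it covers at least ``c_min`` of the
sequences of every family involved AND its permutation E-value is at
most ``alpha`` — coverage prevents a single-family motif plus a handful
of chance sites from passing, and the E-value guards against motifs that
any random set of this size would yield.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import AMINO_ACIDS, SequenceFamily, encode, write_fasta
from . import famsim
from .seqreduce import distance_matrix, reduce, subset_family, merge_families
from .msa import nj_tree, progressive_align, write_alignment
from .conserve import profile, write_profile
from .motifdisc import (
    BackgroundModel,
    Motif,
    discover,
    permutation_evalue,
    scan,
    write_meme,
    write_occurrences,
    _as_dataset,
)


@dataclass(frozen=True)
class FamilyPair:
    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("a family cannot be paired with itself")
        if self.a > self.b:  # canonical unordered form
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)


def family_pairs(families: list[SequenceFamily] | list[str]) -> list[FamilyPair]:
    """All unordered pairs of family names, in deterministic sorted order."""
    names = [f.name if isinstance(f, SequenceFamily) else f for f in families]
    if len(names) < 2:
        raise ValueError("need at least 2 families")
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    pairs = []
    for a, b in itertools.combinations(sorted(names), 2):
        pairs.append(FamilyPair(a, b))
    return pairs


@dataclass
class SharedMotifVerdict:
    set_label: str  # "pooled" or "A+B"
    motif: Motif
    counts: dict[str, int]  # per-family occurrence counts
    coverage: dict[str, float]  # per-family fraction of sequences hit
    e_value: float
    shared: bool


def _best_window_scores(motif: Motif, codes: list[np.ndarray], bg) -> np.ndarray:
    """Best log-odds (bits) window score per sequence; -inf if none fits."""
    LO = np.full((motif.width, 22), -1e30)
    LO[:, :20] = np.log2(motif.ppm) - np.log2(bg.freqs)[None, :]
    out = np.full(len(codes), -np.inf)
    for i, c in enumerate(codes):
        if len(c) < motif.width:
            continue
        G = np.zeros(len(c) - motif.width + 1)
        for k in range(motif.width):
            G += LO[k][c[k : k + len(G)]]
        out[i] = G.max()
    return out


def _calibrated_coverage(
    motif: Motif,
    family: SequenceFamily,
    rng: np.random.Generator,
    null_quantile: float = 0.95,
    n_shuffles: int = 3,
    match_fraction: float = 0.5,
) -> tuple[int, float, float]:
    """Coverage with a shuffle-calibrated threshold and a match floor.

    A sequence counts as covered when its best window score exceeds BOTH

    * the null_quantile of best-window scores over within-sequence
      residue shuffles of the same family (so a diffuse PPM, which
      scores any composition-matched window, covers only
      ~(1 - null_quantile) of any family), and
    * match_fraction of the PPM's maximum attainable log-odds (so a
      window must actually resemble the motif: weak chance resemblances
      between unrelated ancestors sit far below half of the maximum,
      genuine degraded instances far above).

    Returns (hit count above threshold, coverage fraction, threshold)."""
    from .motifdisc import BackgroundModel, _as_dataset

    ds = _as_dataset(family)
    bg = BackgroundModel.from_codes(ds.codes)
    real = _best_window_scores(motif, ds.codes, bg)
    null = []
    for _ in range(n_shuffles):
        shuffled = [c[rng.permutation(len(c))] for c in ds.codes]
        null.append(_best_window_scores(motif, shuffled, bg))
    null = np.concatenate(null)
    null = null[np.isfinite(null)]
    if not len(null):
        return 0, 0.0, float("inf")
    self_max = float((np.log2(motif.ppm) - np.log2(bg.freqs)[None, :]).max(axis=1).sum())
    threshold = max(
        float(np.quantile(null, null_quantile)), match_fraction * self_max
    )
    hits = scan(motif, family, threshold=threshold)
    coverage = float((real > threshold).mean())
    return len(hits), coverage, threshold


def _leave_out_ppm(
    motif: Motif, group: list[SequenceFamily], leave_out: str, pseudocount: float = 0.1
) -> Motif | None:
    """PPM re-estimated from the motif's occurrence windows outside one
    family; None when fewer than 2 such windows exist."""
    seq_by_id = {
        rec.id: rec.sequence for fam in group if fam.name != leave_out for rec in fam
    }
    counts = np.zeros((motif.width, 20))
    n = 0
    for occ in motif.occurrences:
        if occ.family == leave_out:
            continue
        s = seq_by_id.get(occ.sequence_id)
        if s is None:
            continue
        window = s[occ.start - 1 : occ.start - 1 + motif.width]
        if len(window) < motif.width:
            continue
        codes = encode(window)
        if (codes >= 20).any():
            continue
        counts[np.arange(motif.width), codes] += 1
        n += 1
    if n < 2:
        return None
    ppm = (counts + pseudocount) / (n + 20 * pseudocount)
    consensus = "".join(AMINO_ACIDS[a] for a in ppm.argmax(axis=1))
    return Motif(
        ppm=ppm, width=motif.width, consensus=consensus,
        occurrences=[], llr=motif.llr, gamma=motif.gamma,
    )


def shared_motif_search(
    families: list[SequenceFamily],
    c_min: float = 0.25,
    alpha: float = 0.01,
    n_motifs: int = 3,
    w_min: int = 6,
    w_max: int = 30,
    n_perms: int = 99,
    null_quantile: float = 0.95,
    seed: int = 0,
    include_pairs: bool = True,
    **discover_kwargs,
) -> list[SharedMotifVerdict]:
    """Pooled (and optionally pairwise) motif searches with shared verdicts.

    Families should already be reduced to their representative subsets.
    Coverage of family f is *cross-family* coverage, guarded twice:

    * leave-one-family-out — f is scanned with a PPM re-estimated from
      the motif's occurrence windows in the OTHER families of the group,
      so a "mixture" motif that merely glues together family-specific
      signals (a known failure mode of EM on pooled unrelated families)
      collapses, while a genuinely shared motif survives;
    * shuffle-calibrated threshold — a sequence only counts as covered
      when its best window score beats the ``null_quantile`` of scores on
      within-sequence shuffles of the same family, so diffuse PPMs that
      score any composition-matched window cannot claim coverage.

    Discovery itself runs on one half of each family; coverage is
    measured on the held-out halves. Without the split, EM's choice of
    occurrence windows is itself informed by the family being scored
    (it co-aligns windows across families), which inflates leave-out
    coverage on random input. Families with fewer than 6 sequences are
    not split.

    The permutation E-value is computed only for motifs whose coverage
    already passes c_min (motifs failing coverage are not shared
    regardless of significance, and the E-value is the expensive step);
    such motifs report an E-value of +inf.
    """
    by_name = {f.name: f for f in families}
    searches: list[tuple[str, list[SequenceFamily]]] = [
        ("pooled", families)
    ]
    if include_pairs and len(families) >= 2:
        for pair in family_pairs(families):
            searches.append((f"{pair.a}+{pair.b}", [by_name[pair.a], by_name[pair.b]]))

    def _split(fam: SequenceFamily) -> tuple[SequenceFamily, SequenceFamily]:
        if len(fam) < 6:
            return fam, fam
        half = len(fam) // 2
        return (
            SequenceFamily(name=fam.name, records=fam.records[:half]),
            SequenceFamily(name=fam.name, records=fam.records[half:]),
        )

    verdicts = []
    for label, group in searches:
        train_group, valid_group = [], []
        for fam in group:
            tr, va = _split(fam)
            train_group.append(tr)
            valid_group.append(va)
        pooled = merge_families(train_group, name=label)
        motifs = discover(
            pooled,
            w_min=w_min,
            w_max=w_max,
            n_motifs=n_motifs,
            seed=seed,
            **discover_kwargs,
        )
        rng = np.random.default_rng([abs(seed), 555])
        for m in motifs:
            counts, coverage = {}, {}
            for fam_tr, fam_va in zip(train_group, valid_group):
                loo = _leave_out_ppm(m, train_group, leave_out=fam_tr.name)
                if loo is None:
                    coverage[fam_tr.name] = 0.0
                    counts[fam_tr.name] = 0
                    continue
                n_hits, cov, _ = _calibrated_coverage(
                    loo, fam_va, rng, null_quantile=null_quantile
                )
                counts[fam_tr.name] = n_hits
                coverage[fam_tr.name] = cov
            ev = float("inf")
            if min(coverage.values()) >= c_min and n_perms >= 19:
                ev = permutation_evalue(m, pooled, B=n_perms, seed=seed + 13 * m.rank)
                m.e_value = ev
            shared = min(coverage.values()) >= c_min and ev <= alpha
            verdicts.append(
                SharedMotifVerdict(
                    set_label=label,
                    motif=m,
                    counts=counts,
                    coverage=coverage,
                    e_value=ev,
                    shared=shared,
                )
            )
    return verdicts


@dataclass
class MotifComparison:
    family_a: str
    rank_a: int
    family_b: str
    rank_b: int
    score: float
    aligned_a: str
    aligned_b: str


_aligner = None


def _consensus_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
        al.end_gap_score = 0.0
        _aligner = al
    return al if _aligner is None else _aligner


def compare_motif_sets(
    motifs_a: list[Motif],
    motifs_b: list[Motif],
    family_a: str = "A",
    family_b: str = "B",
    top_n: int = 10,
) -> list[MotifComparison]:
    """Every cross-set consensus pair scored by global alignment with free
    end gaps (BLOSUM62, open -11 / extend -1); top_n best returned,
    ties broken by (rank_a, rank_b)."""
    if not motifs_a or not motifs_b:
        raise ValueError("motif sets must be non-empty")
    al = _consensus_aligner()
    rows = []
    for ma in motifs_a:
        for mb in motifs_b:
            res = al.align(ma.consensus, mb.consensus)
            best = res[0]
            rows.append(
                MotifComparison(
                    family_a=family_a,
                    rank_a=ma.rank,
                    family_b=family_b,
                    rank_b=mb.rank,
                    score=float(res.score),
                    aligned_a=str(best[0]),
                    aligned_b=str(best[1]),
                )
            )
    rows.sort(key=lambda r: (-r.score, r.rank_a, r.rank_b))
    return rows[:top_n]


def ppm_correlation(motif_a: Motif, motif_b: Motif) -> float:
    """Secondary comparison mode: best Pearson correlation of the two PPMs
    over all ungapped offsets of the shorter within the longer."""
    a, b = motif_a.ppm, motif_b.ppm
    if len(a) < len(b):
        a, b = b, a
    best = -1.0
    for off in range(len(a) - len(b) + 1):
        window = a[off : off + len(b)]
        r = float(np.corrcoef(window.ravel(), b.ravel())[0, 1])
        best = max(best, r)
    return best


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Configuration of the full two-branch workflow.

    Families come either from ``fasta_paths`` or from the simulator
    (``sim``). The left branch reduces each family, merges the reduced
    sets and builds an NJ tree; the right branch realigns each family,
    profiles conservation and runs the motif stage (per-family discovery,
    pooled and pairwise shared-motif searches, motif-set comparison).
    """

    sim: famsim.SimConfig | None = None
    fasta_paths: list[str] = field(default_factory=list)
    kmer: int = 3
    reduce_target: int = 400
    align_max_rows: int = 200
    n_motifs: int = 30
    w_min: int = 6
    w_max: int = 30
    n_perms: int = 99
    shared_n_motifs: int = 2
    c_min: float = 0.25
    alpha: float = 0.01
    top_n: int = 10
    seed: int = 0
    refine: bool = True


@dataclass
class PipelineResult:
    families: list[SequenceFamily]
    reduced: list[SequenceFamily]
    tree_newick: str
    alignments: dict[str, object]
    per_family_motifs: dict[str, list[Motif]]
    comparisons: dict[str, list[MotifComparison]]
    verdicts: list[SharedMotifVerdict]
    manifest: list[tuple[str, str]]


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute both branches of the workflow; any stage failure aborts with
    the stage name after writing a partial manifest."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = [("seed", str(config.seed))]
    stage = "load"

    def _fail(exc: Exception):
        if out is not None:
            _write_manifest(manifest + [("failed_stage", stage)], out / "manifest.tsv")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    try:
        if config.sim is not None:
            families = famsim.simulate_families(config.sim)
        else:
            from ._seq import read_fasta

            families = [read_fasta(p) for p in config.fasta_paths]
        manifest.append(("n_families", str(len(families))))

        stage = "reduce"
        reduced = []
        for fam in families:
            dm = distance_matrix(fam, k=config.kmer)
            res = reduce(dm, config.reduce_target)
            sub = subset_family(fam, res.kept)
            reduced.append(sub)
            if out is not None:
                write_fasta(sub.records, out / f"{fam.name}.kept.fasta")
        manifest.append(("reduced_sizes", ",".join(str(len(r)) for r in reduced)))

        stage = "tree"
        merged = merge_families(reduced)
        dm_m = distance_matrix(merged, k=config.kmer)
        tree = nj_tree(dm_m)
        newick = str(tree).strip()
        if out is not None:
            (out / "tree.nwk").write_text(newick + "\n")
        manifest.append(("merged_size", str(len(merged))))

        stage = "align"
        alignments = {}
        for fam in reduced:
            sub = fam
            if len(sub) > config.align_max_rows:
                sub = SequenceFamily(name=fam.name, records=fam.records[: config.align_max_rows])
            aln = progressive_align(sub, k=config.kmer)
            alignments[fam.name] = aln
            if out is not None:
                write_alignment(aln, out / f"{fam.name}.aln.fasta")

        stage = "conservation"
        for name, aln in alignments.items():
            prof = profile(aln)
            if out is not None:
                write_profile(prof, out / f"{name}.conservation.tsv")

        stage = "motifs"
        per_family: dict[str, list[Motif]] = {}
        for fam in reduced:
            motifs = discover(
                fam,
                w_min=config.w_min,
                w_max=config.w_max,
                n_motifs=config.n_motifs,
                seed=config.seed,
                refine=config.refine,
            )
            per_family[fam.name] = motifs
            if out is not None:
                bg = BackgroundModel.from_codes(_as_dataset(fam).codes)
                write_meme(motifs, bg, out / f"{fam.name}.motifs.meme")
                write_occurrences(motifs, out / f"{fam.name}.occurrences.tsv")
        manifest.append(
            ("motifs_per_family", ",".join(str(len(v)) for v in per_family.values()))
        )

        stage = "shared"
        verdicts = shared_motif_search(
            reduced,
            c_min=config.c_min,
            alpha=config.alpha,
            n_motifs=config.shared_n_motifs,
            w_min=config.w_min,
            w_max=config.w_max,
            n_perms=config.n_perms,
            seed=config.seed,
            refine=config.refine,
        )
        if out is not None:
            write_verdicts(verdicts, out / "verdicts.tsv")
        manifest.append(("n_shared", str(sum(v.shared for v in verdicts))))

        stage = "compare"
        comparisons = {}
        names = sorted(per_family)
        for pair in family_pairs(names):
            comparisons[f"{pair.a}+{pair.b}"] = compare_motif_sets(
                per_family[pair.a],
                per_family[pair.b],
                family_a=pair.a,
                family_b=pair.b,
                top_n=config.top_n,
            )
        if out is not None:
            write_comparisons(comparisons, out / "comparisons.tsv")

        if out is not None:
            _write_manifest(manifest, out / "manifest.tsv")
    except RuntimeError:
        raise
    except Exception as exc:
        _fail(exc)
    return PipelineResult(
        families=families,
        reduced=reduced,
        tree_newick=newick,
        alignments=alignments,
        per_family_motifs=per_family,
        comparisons=comparisons,
        verdicts=verdicts,
        manifest=manifest,
    )


def _write_manifest(items: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in items:
            fh.write(f"{k}\t{v}\n")


def write_verdicts(verdicts: list[SharedMotifVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "set\trank\tconsensus\twidth\te_value\tmin_coverage\tcoverages\tshared\n"
        )
        for v in verdicts:
            cov = ",".join(f"{k}:{x:.3f}" for k, x in sorted(v.coverage.items()))
            fh.write(
                f"{v.set_label}\t{v.motif.rank}\t{v.motif.consensus}\t"
                f"{v.motif.width}\t{v.e_value:.4g}\t"
                f"{min(v.coverage.values()):.3f}\t{cov}\t{int(v.shared)}\n"
            )


def write_comparisons(
    comparisons: dict[str, list[MotifComparison]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tfamily_a\trank_a\tfamily_b\trank_b\tscore\taligned_a\taligned_b\n")
        for pair, rows in sorted(comparisons.items()):
            for r in rows:
                fh.write(
                    f"{pair}\t{r.family_a}\t{r.rank_a}\t{r.family_b}\t{r.rank_b}\t"
                    f"{r.score:.2f}\t{r.aligned_a}\t{r.aligned_b}\n"
                )
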