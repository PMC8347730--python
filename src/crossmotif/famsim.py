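"""Synthetic protein-family simulator.

Emulates the statistical structure of large homologue harvests: each
family descends from its own random ancestor by point substitution and
short indels, so families are mutually unrelated while sequences within a
family share recognisable similarity. Short degenerate motifs can be
planted into chosen families — within one family, repeated within a
sequence, or shared across families — at a configurable occupancy and
per-position degradation, with ground-truth coordinates recorded so that
downstream reduction, alignment, conservation and motif-discovery stages
can be validated without any external data.

Determinism: one global seed; each family consumes an independent
substream derived from (seed, family index), so adding a family never
perturbs the sequences of earlier families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import (
    AMINO_ACIDS,
    AA_INDEX,
    N_AA,
    PlantedSite,
    SequenceFamily,
    SequenceRecord,
    write_fasta,
)

_PATTERN_TOKEN = re.compile(r"\[([A-WY]{2,})\]|([A-WY])|(X)")

#: hard cap on indel event length, residues
MAX_INDEL_LEN = 10


def parse_pattern(pattern: str) -> list[tuple[str, str | None]]:
    """Parse a degenerate pattern into per-position tokens.

    Tokens are ``("fixed", letter)``, ``("class", residues)`` and
    ``("any", None)`` for X. Only the 20 canonical residues are allowed
    inside classes and as fixed letters.
    """
    positions: list[tuple[str, str | None]] = []
    pos = 0
    while pos < len(pattern):
        m = _PATTERN_TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"invalid pattern syntax at offset {pos}: {pattern!r}")
        cls, fixed, wild = m.groups()
        if cls is not None:
            bad = [c for c in cls if c not in AA_INDEX]
            if bad:
                raise ValueError(f"invalid residues {bad} in class [{cls}]")
            positions.append(("class", cls))
        elif fixed is not None:
            if fixed not in AA_INDEX:
                raise ValueError(f"invalid residue {fixed!r} in pattern")
            positions.append(("fixed", fixed))
        else:
            assert wild == "X"
            positions.append(("any", None))
        pos = m.end()
    return positions


@dataclass
class MotifPlant:
    """Specification of a motif to plant into one or more families.

    occupancy is realised as an exact count round(occupancy * n) of
    carrier sequences per target family (not per-sequence Bernoulli), so
    recovery statistics downstream are non-flaky. degradation is the
    per-position probability that the instantiated residue is replaced by
    a uniformly random one.
    """

    pattern: str
    target_families: list[int]
    occupancy: float = 1.0
    copies_per_sequence: int = 1
    degradation: float = 0.0
    #: anchored copies share one relative position per family (homologous
    #: placement, alignable into common columns); unanchored copies land at
    #: an independent uniform position in every sequence
    anchored: bool = False

    def __post_init__(self) -> None:
        self.positions = parse_pattern(self.pattern)
        w = len(self.positions)
        if not 6 <= w <= 30:
            raise ValueError(f"pattern length {w} outside the motif width bounds [6, 30]")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.copies_per_sequence < 1:
            raise ValueError("copies_per_sequence must be >= 1")
        if not 0.0 <= self.degradation < 1.0:
            raise ValueError("degradation must be in [0, 1)")

    @property
    def width(self) -> int:
        return len(self.positions)


@dataclass
class SimConfig:
    n_families: int = 3
    seqs_per_family: int = 200
    ancestor_length: int = 300
    substitution_rate: float = 0.3
    indel_rate: float = 0.02
    indel_length_mean: float = 2.0
    planted_motifs: list[MotifPlant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.seqs_per_family < 1:
            raise ValueError("n_families and seqs_per_family must be >= 1")
        if self.ancestor_length < 30:
            raise ValueError("ancestor_length must be >= 30")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0.0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must be in [0, 0.2]")
        for plant in self.planted_motifs:
            if plant.width > self.ancestor_length:
                raise ValueError(
                    f"motif pattern of width {plant.width} longer than "
                    f"ancestor_length {self.ancestor_length}"
                )


def _instantiate(plant: MotifPlant, rng: np.random.Generator) -> tuple[str, frozenset[int]]:
    """Draw one concrete copy of a degenerate pattern, with degradation."""
    out = []
    degraded = []
    for i, (kind, arg) in enumerate(plant.positions):
        if kind == "fixed":
            res = arg
        elif kind == "class":
            res = arg[rng.integers(len(arg))]
        else:
            res = AMINO_ACIDS[rng.integers(N_AA)]
        if plant.degradation > 0 and rng.random() < plant.degradation:
            res = AMINO_ACIDS[rng.integers(N_AA)]
            degraded.append(i)
        out.append(res)
    return "".join(out), frozenset(degraded)


def _mutate(ancestor: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply per-site substitutions and indel events to an encoded sequence."""
    seq = ancestor.copy()
    if cfg.substitution_rate > 0:
        hit = rng.random(len(seq)) < cfg.substitution_rate
        if hit.any():
            # uniform over the 19 alternative residues
            shift = rng.integers(1, N_AA, size=int(hit.sum()))
            seq[hit] = (seq[hit] + shift) % N_AA
    if cfg.indel_rate > 0:
        n_events = rng.binomial(len(seq), cfg.indel_rate)
        for _ in range(n_events):
            # geometric with the configured mean, capped
            p = min(1.0, 1.0 / max(cfg.indel_length_mean, 1.0))
            length = int(min(rng.geometric(p), MAX_INDEL_LEN))
            if rng.random() < 0.5 and len(seq) > length + 10:
                pos = int(rng.integers(0, len(seq) - length))
                seq = np.delete(seq, slice(pos, pos + length))
            else:
                pos = int(rng.integers(0, len(seq) + 1))
                ins = rng.integers(0, N_AA, size=length).astype(seq.dtype)
                seq = np.concatenate([seq[:pos], ins, seq[pos:]])
    return seq


def _insert_copy(
    record: SequenceRecord, motif_index: int, copy: str, degraded: frozenset[int],
    rng: np.random.Generator, rel_pos: float | None = None,
) -> None:
    """Insert one motif copy at a uniform position >= 1 residue from either
    end (or at the fixed relative position rel_pos), never splitting a
    previously planted copy; shifts earlier truth coordinates that lie
    downstream of the insertion point."""
    seq = record.sequence
    if rel_pos is not None:
        start = 2 + int(round(rel_pos * (len(seq) - 1)))
        start = min(max(start, 2), len(seq))
        # never split an existing planted copy
        for site in record.truth:
            if site.start < start <= site.end:
                start = site.end + 1
        start = min(start, len(seq))
    else:
        for _ in range(1000):
            start = int(rng.integers(2, len(seq) + 1))  # 1-based insertion start
            if all(not (site.start < start <= site.end) for site in record.truth):
                break
        else:  # pragma: no cover - pathological saturation
            raise RuntimeError(f"no valid insertion point left in {record.id}")
    record.sequence = seq[: start - 1] + copy + seq[start - 1 :]
    for site in record.truth:
        if site.start >= start:
            site.start += len(copy)
    record.truth.append(
        PlantedSite(motif_index=motif_index, start=start, length=len(copy), degraded=degraded)
    )


def simulate_families(config: SimConfig) -> list[SequenceFamily]:
    """Simulate families of diverged homologues with optional planted motifs.

    Returns n_families families named ``fam0 .. fam{n-1}``, each with
    seqs_per_family records diverged independently from the family's own
    random ancestor. Identical configs (including seed) give byte-identical
    output.
    """
    families: list[SequenceFamily] = []
    for fam_idx in range(config.n_families):
        rng = np.random.default_rng([config.seed, fam_idx])
        name = f"fam{fam_idx}"
        ancestor = rng.integers(0, N_AA, size=config.ancestor_length)
        records = []
        for s in range(config.seqs_per_family):
            codes = _mutate(ancestor, config, rng)
            records.append(
                SequenceRecord(
                    id=f"{name}_s{s:04d}",
                    sequence="".join(AMINO_ACIDS[c] for c in codes),
                    family=name,
                )
            )
        for motif_index, plant in enumerate(config.planted_motifs):
            if fam_idx not in plant.target_families:
                continue
            n_carriers = int(round(plant.occupancy * len(records)))
            carriers = rng.choice(len(records), size=n_carriers, replace=False)
            rel_positions = (
                sorted(rng.random(plant.copies_per_sequence) * 0.9)
                if plant.anchored
                else [None] * plant.copies_per_sequence
            )
            for ci in sorted(carriers):
                for rel in rel_positions:
                    copy, degraded = _instantiate(plant, rng)
                    _insert_copy(records[ci], motif_index, copy, degraded, rng, rel)
        families.append(SequenceFamily(name=name, records=records))
    return families


def write_truth(families: list[SequenceFamily], path: str | Path) -> None:
    """Write the planted-copy ground truth as TSV (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tfamily\tmotif_index\tstart\tend\n")
        for fam in families:
            for rec in fam:
                for site in rec.truth:
                    fh.write(
                        f"{rec.id}\t{fam.name}\t{site.motif_index}\t"
                        f"{site.start}\t{site.end}\n"
                    )


def write_config(config: SimConfig, path: str | Path) -> None:
    """Echo the simulation parameters as a flat key=value text file."""
    lines = [
        f"n_families={config.n_families}",
        f"seqs_per_family={config.seqs_per_family}",
        f"ancestor_length={config.ancestor_length}",
        f"substitution_rate={config.substitution_rate}",
        f"indel_rate={config.indel_rate}",
        f"indel_length_mean={config.indel_length_mean}",
        f"seed={config.seed}",
    ]
    for i, plant in enumerate(config.planted_motifs):
        fams = ",".join(str(f) for f in plant.target_families)
        lines.append(
            f"plant{i}={plant.pattern}@{fams}:{plant.occupancy}:"
            f"{plant.copies_per_sequence}:{plant.degradation}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_families(families: list[SequenceFamily], outdir: str | Path) -> list[Path]:
    """Write one 60-column-wrapped FASTA per family; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fam in families:
        p = outdir / f"{fam.name}.fasta"
        write_fasta(fam.records, p)
        paths.append(p)
    return paths
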