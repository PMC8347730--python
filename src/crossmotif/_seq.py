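"""Shared sequence plumbing: alphabet, records, families, FASTA IO.

The canonical alphabet is the 20 amino acids in the fixed order
``ACDEFGHIKLMNPQRSTVWY``; integer encodings used throughout the package
index into this string. Ambiguity codes (B/Z/X/U/J/O) are tolerated on
input where a function documents it, mapped to X, and excluded from all
frequency estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20
GAP = "-"
#: integer code for a gap in encoded alignment matrices
GAP_CODE = 20
#: integer code for a masked residue (motifdisc masking)
MASK_CODE = 21
AMBIGUOUS = set("BZXUJO")

_ENCODE = np.full(256, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _ENCODE[ord(_a)] = _i
_ENCODE[ord(GAP)] = GAP_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int8 codes (gap allowed).

    Raises ValueError on any character outside the 20 canonical residues
    plus '-'.
    """
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq if c not in AA_INDEX and c != GAP})
        raise ValueError(f"non-canonical residues in sequence: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    table = AMINO_ACIDS + GAP
    return "".join(table[c] for c in codes)


@dataclass
class PlantedSite:
    """Ground-truth coordinates of one planted motif copy.

    start is 1-based on the final (post-insertion) sequence; degraded
    holds 0-based offsets within the motif where the pattern residue was
    replaced by a random one.
    """

    motif_index: int
    start: int
    length: int
    degraded: frozenset[int] = frozenset()

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    family: str
    truth: list[PlantedSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceFamily:
    """A named, ordered collection of protein sequence records."""

    name: str
    records: list[SequenceRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path: str | Path, family: str | None = None) -> SequenceFamily:
    """Read a FASTA file into a SequenceFamily.

    Ambiguity codes are replaced by X only if present; X itself is not in
    the canonical alphabet, so families destined for simulation-grade
    statistics should be clean. The family name defaults to the file stem.
    """
    path = Path(path)
    name = family if family is not None else path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), family=name))
    return SequenceFamily(name=name, records=records)
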