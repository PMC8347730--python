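"""Pairwise k-mer dissimilarities and diversity-preserving set reduction.

A family is reduced to ``k`` representatives by sorting all pairwise
dissimilarities, visiting pairs from the most similar upward and, for each
pair whose members both survive, deleting one member — the one that sits
closer to the rest of the surviving set — until the target size is
reached. This removes redundancy among near-identical sequences while
keeping the most even spread of representatives across sequence space.

Dissimilarity between two unaligned sequences is a k-mer set overlap:
``d = 1 - |Ka ∩ Kb| / min(|Ka|, |Kb|)`` over sets of distinct k-mers, a
fast alignment-free stand-in for alignment-derived distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from ._seq import SequenceFamily, SequenceRecord


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities in [0, 1], zero diagonal."""

    ids: list[str]
    data: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sequence IDs in distance matrix")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self._index[a], self._index[b]])

    def index(self, sid: str) -> int:
        return self._index[sid]

    def write_phylip(self, path: str | Path) -> None:
        """Write in PHYLIP square distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.data):
                fh.write(sid + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids=ids, data=np.array(rows))


@dataclass
class ReductionResult:
    kept: list[str]
    removed: list[tuple[str, str, float]]  # (removed id, partner id, distance)


def _kmer_set(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Dissimilarity 1 - |Ka ∩ Kb| / min(|Ka|, |Kb|) over distinct k-mers."""
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def distance_matrix(family: SequenceFamily, k: int = 3) -> DistanceMatrix:
    """All pairwise k-mer distances of a family.

    Vectorised through a sparse sequence × k-mer presence matrix, so
    families of several thousand members are handled in seconds.
    """
    ids = family.ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs in family")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = family.sequences()
    vocab: dict[str, int] = {}
    indptr = [0]
    indices: list[int] = []
    for s in seqs:
        if len(s) < k:
            raise ValueError(f"sequence shorter than k={k}")
        for kmer in {s[i : i + k] for i in range(len(s) - k + 1)}:
            indices.append(vocab.setdefault(kmer, len(vocab)))
        indptr.append(len(indices))
    presence = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.float32), np.array(indices), np.array(indptr)),
        shape=(len(seqs), len(vocab)),
    )
    inter = (presence @ presence.T).toarray()
    sizes = np.asarray(presence.sum(axis=1)).ravel()
    mins = np.minimum.outer(sizes, sizes)
    d = 1.0 - inter / mins
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite float noise
    d = np.maximum(np.minimum(d, d.T), 0.0)
    return DistanceMatrix(ids=list(ids), data=d)


def _sorted_pairs(d: np.ndarray, rank: np.ndarray) -> np.ndarray:
    """Upper-triangle pairs sorted by (distance, id, id) lexicographic.

    rank[i] is the lexicographic rank of id i; each returned pair (i, j)
    has rank[i] < rank[j].
    """
    iu, ju = np.triu_indices(d.shape[0], k=1)
    swap = rank[iu] > rank[ju]
    iu2 = np.where(swap, ju, iu)
    ju2 = np.where(swap, iu, ju)
    order = np.lexsort((rank[ju2], rank[iu2], d[iu, ju]))
    return np.stack([iu2[order], ju2[order]], axis=1)


def reduce(dm: DistanceMatrix, target_size: int) -> ReductionResult:
    """Greedy redundancy reduction to ``target_size`` representatives.

    Pairs are visited in ascending distance order; from each pair whose
    members both survive, the member with the smaller total distance to
    the surviving set (the more central one) is removed, keeping the
    outliers and thereby the spread. Ties on total distance remove the
    lexicographically smaller ID. Deterministic.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    n = len(dm)
    if n == 0:
        raise ValueError("empty distance matrix")
    if target_size >= n:
        return ReductionResult(kept=list(dm.ids), removed=[])
    order = np.argsort(dm.ids)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    d = dm.data
    pairs = _sorted_pairs(d, rank)
    alive = np.ones(n, dtype=bool)
    rowsum = d.sum(axis=1)
    removed: list[tuple[str, str, float]] = []
    n_alive = n
    for i, j in pairs:
        if n_alive <= target_size:
            break
        if not (alive[i] and alive[j]):
            continue
        si, sj = rowsum[i], rowsum[j]
        if si < sj:
            out, partner = i, j
        elif sj < si:
            out, partner = j, i
        else:  # tie: remove the lexicographically smaller ID
            out, partner = (i, j) if rank[i] < rank[j] else (j, i)
        alive[out] = False
        rowsum -= d[:, out]
        n_alive -= 1
        removed.append((dm.ids[out], dm.ids[partner], float(d[i, j])))
    kept = [dm.ids[i] for i in range(n) if alive[i]]
    return ReductionResult(kept=kept, removed=removed)


def select_nearest(dm: DistanceMatrix, reference_id: str, n: int) -> list[str]:
    """The n ids nearest to the reference (reference itself included).

    Ties broken lexicographically; returned in ascending (distance, id)
    order.
    """
    if reference_id not in dm._index:
        raise KeyError(f"unknown reference {reference_id!r}")
    if n > len(dm):
        raise ValueError(f"n={n} exceeds matrix size {len(dm)}")
    ref = dm.index(reference_id)
    keyed = sorted(zip(dm.data[ref], dm.ids))
    return [sid for _, sid in keyed[:n]]


def subset_family(family: SequenceFamily, ids: list[str]) -> SequenceFamily:
    """Restrict a family to the given ids, preserving their given order."""
    by_id = {r.id: r for r in family}
    return SequenceFamily(name=family.name, records=[by_id[i] for i in ids])


def merge_families(families: list[SequenceFamily], name: str = "merged") -> SequenceFamily:
    """Concatenate families, preserving family tags.

    ID collisions are resolved by prefixing the family name; collisions
    are reported on the returned records, never fatal.
    """
    seen: set[str] = set()
    records: list[SequenceRecord] = []
    for fam in families:
        for rec in fam:
            rid = rec.id
            if rid in seen:
                rid = f"{fam.name}.{rec.id}"
            seen.add(rid)
            records.append(
                SequenceRecord(id=rid, sequence=rec.sequence, family=rec.family, truth=rec.truth)
            )
    return SequenceFamily(name=name, records=records)
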