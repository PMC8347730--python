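"""Neighbor-joining trees and progressive multiple alignment.

The aligner is a classic guide-tree progressive profile aligner: a
neighbor-joining tree is built from alignment-free k-mer distances,
midpoint-rooted, and profiles are merged in post-order with a
profile-profile Gotoh affine-gap dynamic programme. Columns are scored as
the expected pairwise substitution score between the two profile
distributions (sum-of-pairs expectation) under BLOSUM62; gap frequencies
enter as a 21st symbol with zero substitution score. This recovers the
exact pairwise affine-gap optimum in the two-sequence case and scales to
family-sized sets (thousands of rows) for desk work; no iterative
refinement is attempted.

Externally computed alignments (aligned FASTA) can be imported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from Bio import SeqIO
from Bio.Align import substitution_matrices
from skbio import TreeNode

from ._seq import AMINO_ACIDS, GAP, GAP_CODE, SequenceFamily, decode, encode
from .seqreduce import DistanceMatrix, distance_matrix


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster representatives (a cluster
    is represented by its smallest leaf label). Negative branch lengths
    are clamped to 0. The returned tree is the usual rooted
    representation of the unrooted NJ tree (trifurcating root for n >= 3).
    """
    n = len(dm)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 sequences")
    nodes = [TreeNode(name=sid) for sid in dm.ids]
    reps = list(dm.ids)  # lexicographic representative per cluster
    D = dm.data.astype(np.float64).copy()

    def _pick(Q: np.ndarray) -> tuple[int, int]:
        m = Q.shape[0]
        qmin = Q.min()
        best = None
        for i, j in zip(*np.nonzero(Q == qmin)):
            if i >= j:
                continue
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, (int(i), int(j)))
        return best[1]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # group the row sums so Q is bit-symmetric (a-b-c != a-c-b in floats)
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        i, j = _pick(Q)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        D = D2

    if len(nodes) == 2:
        nodes[0].length = float(D[0, 1])
        nodes[1].length = 0.0
        return TreeNode(children=nodes)
    # three clusters: solve the star lengths exactly
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
    return TreeNode(children=nodes)


def tip_distance(tree: TreeNode, a: str, b: str) -> float:
    """Path length between two leaves."""
    return float(tree.find(a).distance(tree.find(b)))


def is_monophyletic(tree: TreeNode, tip_names: set[str]) -> bool:
    """True if the tips form a clade of the *unrooted* tree.

    Some edge must bipartition the leaves into exactly this set versus the
    rest; the rooted clade test alone would fail a group that happens to
    contain the arbitrary root.
    """
    all_tips = {t.name for t in tree.tips()}
    missing = set(tip_names) - all_tips
    if missing:
        raise KeyError(f"tip names missing from tree: {sorted(missing)}")
    target = set(tip_names)
    if len(target) <= 1 or target == all_tips:
        return True
    complement = all_tips - target
    for node in tree.postorder(include_self=False):
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if below == target or below == complement:
            return True
    return False


# ---------------------------------------------------------------------------
# alignment container and IO


@dataclass
class Alignment:
    """Gapped sequence matrix with equal-length rows ('-' gaps only)."""

    ids: list[str]
    rows: list[str]
    families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, expected {L}"
                )
        if not self.families:
            self.families = [""] * len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def ungapped(self, sid: str) -> str:
        return self.row(sid).replace(GAP, "")

    def to_matrix(self) -> np.ndarray:
        """int8 matrix, gap encoded as 20."""
        return np.stack([encode(r) for r in self.rows])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def read_alignment(path: str | Path, families: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA; raises on ragged rows, naming the record."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no records in {path}")
    L = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != L:
            raise ValueError(f"ragged alignment in {path}: record {sid!r}")
    fams = [families.get(i, "") for i in ids] if families else None
    return Alignment(ids=ids, rows=rows, families=fams or [""] * len(ids))


# ---------------------------------------------------------------------------
# progressive alignment


@dataclass
class AlignParams:
    gap_open: float = -11.0
    gap_extend: float = -1.0
    matrix: str = "BLOSUM62"


def _submatrix(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    B = np.zeros((20, 20), dtype=np.float32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            B[i, j] = m[a, b]
    return B


@njit(cache=True)
def _gotoh(S, gap_open, gap_extend):  # pragma: no cover - jitted
    """Global affine-gap DP over a precomputed column-pair score matrix.

    A gap run of length L costs gap_open + (L-1)*gap_extend. Returns the
    optimal score and a traceback pointer matrix: state 0 = diagonal,
    1 = gap in B (consume A row), 2 = gap in A (consume B column).
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        ptr[1, i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        ptr[2, 0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal
            best = M[i - 1, j - 1]
            arg = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                arg = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                arg = 2
            M[i, j] = best + S[i - 1, j - 1]
            ptr[0, i, j] = arg
            # gap in B: consume A row i
            o = M[i - 1, j] + gap_open
            e = Ix[i - 1, j] + gap_extend
            o2 = Iy[i - 1, j] + gap_open
            if e >= o and e >= o2:
                Ix[i, j] = e
                ptr[1, i, j] = 1
            elif o >= o2:
                Ix[i, j] = o
                ptr[1, i, j] = 0
            else:
                Ix[i, j] = o2
                ptr[1, i, j] = 2
            # gap in A: consume B column j
            o = M[i, j - 1] + gap_open
            e = Iy[i, j - 1] + gap_extend
            o2 = Ix[i, j - 1] + gap_open
            if e >= o and e >= o2:
                Iy[i, j] = e
                ptr[2, i, j] = 2
            elif o >= o2:
                Iy[i, j] = o
                ptr[2, i, j] = 0
            else:
                Iy[i, j] = o2
                ptr[2, i, j] = 1
    score = M[n, m]
    state = 0
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    return score, state, ptr


def _traceback(ptr: np.ndarray, state: int, n: int, m: int) -> list[int]:
    """Alignment path as a list of moves (0 diag, 1 down, 2 right), 5'->3'."""
    i, j = n, m
    moves = []
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        moves.append(state)
        if state == 0:
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            i -= 1
            state = 0 if prev == 0 else prev
        else:
            j -= 1
            state = 0 if prev == 0 else prev
    moves.reverse()
    return moves


def _profile(block: np.ndarray) -> np.ndarray:
    """Per-column frequency of codes 0..20 (20 = gap); shape (L, 21)."""
    L = block.shape[1]
    prof = np.zeros((L, 21), dtype=np.float32)
    for c in range(21):
        prof[:, c] = (block == c).mean(axis=0)
    return prof


def _merge(blockA: np.ndarray, blockB: np.ndarray, B: np.ndarray, params: AlignParams):
    pa = _profile(blockA)[:, :20]
    pb = _profile(blockB)[:, :20]
    S = (pa @ B @ pb.T).astype(np.float64)
    score, state, ptr = _gotoh(S, params.gap_open, params.gap_extend)
    moves = _traceback(ptr, state, blockA.shape[1], blockB.shape[1])
    L = len(moves)
    nA, nB = blockA.shape[0], blockB.shape[0]
    out = np.full((nA + nB, L), GAP_CODE, dtype=np.int8)
    ia = ib = 0
    for col, mv in enumerate(moves):
        if mv in (0, 1):
            out[:nA, col] = blockA[:, ia]
            ia += 1
        if mv in (0, 2):
            out[nA:, col] = blockB[:, ib]
            ib += 1
    return out, score


def progressive_align(
    family: SequenceFamily,
    guide: TreeNode | None = None,
    params: AlignParams | None = None,
    k: int = 3,
) -> Alignment:
    """Guide-tree progressive profile alignment of a family.

    If no guide tree is given, one is built by neighbor joining on k-mer
    distances and midpoint-rooted. Guide leaves must match the family ids
    exactly. Ungapping any output row reproduces its input sequence.
    """
    params = params or AlignParams()
    if len(family) == 1:
        rec = family[0]
        return Alignment(ids=[rec.id], rows=[rec.sequence], families=[rec.family])
    if guide is None:
        dm = distance_matrix(family, k=k)
        guide = nj_tree(dm)
        try:
            rooted = guide.root_at_midpoint()
            # midpoint rooting can degenerate on tiny or zero-length trees
            if {t.name for t in rooted.tips()} == set(family.ids):
                guide = rooted
        except Exception:
            pass  # keep the NJ rooting
    tips = {t.name for t in guide.tips()}
    if tips != set(family.ids):
        raise ValueError("guide tree leaves do not match family ids")
    B = _submatrix(params.matrix)
    by_id = {r.id: r for r in family}

    def build(node: TreeNode) -> tuple[list[str], np.ndarray]:
        if node.is_tip():
            return [node.name], encode(by_id[node.name].sequence)[None, :]
        child_results = [build(c) for c in node.children]
        ids, block = child_results[0]
        for ids2, block2 in child_results[1:]:
            block, _ = _merge(block, block2, B, params)
            ids = ids + ids2
        return ids, block

    ids, block = build(guide)
    # restore input record order
    order = {sid: i for i, sid in enumerate(ids)}
    rows = [decode(block[order[r.id]]) for r in family]
    return Alignment(
        ids=list(family.ids), rows=rows, families=[r.family for r in family]
    )


def pairwise_score(a: str, b: str, params: AlignParams | None = None) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    params = params or AlignParams()
    B = _submatrix(params.matrix)
    ca, cb = encode(a), encode(b)
    S = B[np.ix_(ca, cb)].astype(np.float64)
    score, _, _ = _gotoh(S, params.gap_open, params.gap_extend)
    return float(score)


def identity_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """1 - fractional identity over columns where both rows have residues.

    Offered as an alternative to k-mer distances for tree building from an
    existing alignment.
    """
    mat = aln.to_matrix()
    n = len(aln.ids)
    d = np.zeros((n, n))
    nongap = mat != GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            nb = int(both.sum())
            ident = float((mat[i, both] == mat[j, both]).mean()) if nb else 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(ids=list(aln.ids), data=d)
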