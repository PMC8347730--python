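"""Per-column conservation, reference masking and consensus extraction.

Conservation of an alignment column is measured by Shannon entropy in
base 20,

    S = - sum_a p_a log20 p_a,

where p_a is the frequency of amino-acid type a among the residues of the
column. The base-20 logarithm normalises S to [0, 1]: S = 0 for a fully
conserved column and S = 1 for a column uniform over all 20 types. Gaps
are excluded from p_a and reported separately as a gap fraction;
ambiguity codes (B/Z/X/U/J/O) are likewise excluded. Columns with no
residues at all carry an undefined entropy flag rather than a number.

A degenerate consensus pattern summarises a column span: a column becomes
a fixed letter when its top residue reaches the t_fix frequency, a
bracketed class of the 2-3 top residues when they jointly reach t_class,
and the wildcard X otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import AMBIGUOUS, AMINO_ACIDS, AA_INDEX, GAP, N_AA
from .msa import Alignment

#: columns with fewer than this fraction of residues are flagged low-coverage
LOW_COVERAGE = 0.2


@dataclass
class ColumnDistribution:
    p_a: np.ndarray  # length-20 frequencies over residues present
    n_residues: int
    gap_fraction: float

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, dtype=np.float64)
        if self.n_residues > 0 and abs(self.p_a.sum() - 1.0) > 1e-9:
            raise ValueError("column distribution does not sum to 1")


@dataclass
class ConservationProfile:
    """Per-column entropies and distributions of an alignment.

    entropy[i] is NaN exactly where defined[i] is False (all-gap column).
    col_to_ref maps alignment column -> 1-based reference residue number
    (0 where the reference has a gap) when a reference was supplied.
    """

    columns: list[ColumnDistribution]
    entropy: np.ndarray
    defined: np.ndarray
    reference_id: str | None = None
    col_to_ref: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.columns)

    def low_coverage(self) -> np.ndarray:
        occ = np.array(
            [1.0 - c.gap_fraction for c in self.columns]
        )
        return occ < LOW_COVERAGE


def column_entropy(dist: ColumnDistribution) -> float:
    """Base-20 Shannon entropy of one column; raises on all-gap columns."""
    if dist.n_residues == 0:
        raise ValueError("entropy undefined for an all-gap column")
    p = dist.p_a[dist.p_a > 0]
    return float(-(p * (np.log(p) / np.log(N_AA))).sum())


def _column_dist(col: str) -> ColumnDistribution:
    counts = np.zeros(N_AA)
    n_gap = 0
    for c in col:
        if c == GAP:
            n_gap += 1
        elif c in AA_INDEX:
            counts[AA_INDEX[c]] += 1
        elif c in AMBIGUOUS:
            # treated as X: excluded from p_a, not counted as a gap either
            n_gap += 0
        else:
            raise ValueError(f"unexpected symbol {c!r} in alignment column")
    n = int(counts.sum())
    p = counts / n if n else counts
    return ColumnDistribution(p_a=p, n_residues=n, gap_fraction=n_gap / len(col))


def profile(aln: Alignment, reference_id: str | None = None) -> ConservationProfile:
    """Column distributions and entropies for every alignment column."""
    cols = ["".join(row[i] for row in aln.rows) for i in range(aln.n_columns)]
    dists = [_column_dist(c) for c in cols]
    entropy = np.array(
        [column_entropy(d) if d.n_residues else np.nan for d in dists]
    )
    defined = np.array([d.n_residues > 0 for d in dists])
    col_to_ref = None
    if reference_id is not None:
        ref = aln.row(reference_id)
        col_to_ref = np.zeros(aln.n_columns, dtype=np.int64)
        r = 0
        for i, c in enumerate(ref):
            if c != GAP:
                r += 1
                col_to_ref[i] = r
    return ConservationProfile(
        columns=dists,
        entropy=entropy,
        defined=defined,
        reference_id=reference_id,
        col_to_ref=col_to_ref,
    )


def mask_to_reference(aln: Alignment, reference_id: str) -> Alignment:
    """Keep exactly the columns where the reference row has a residue."""
    if reference_id not in aln.ids:
        raise KeyError(f"unknown reference {reference_id!r}")
    ref = aln.row(reference_id)
    keep = [i for i, c in enumerate(ref) if c != GAP]
    rows = ["".join(row[i] for i in keep) for row in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows, families=list(aln.families))


def map_reference_span(
    aln: Alignment, reference_id: str, start: int, end: int
) -> list[int]:
    """Alignment columns (0-based) holding reference residues start..end.

    Coordinates are 1-based inclusive on the ungapped reference; the
    returned list has exactly end - start + 1 entries, in order.
    """
    if reference_id not in aln.ids:
        raise KeyError(f"unknown reference {reference_id!r}")
    ref = aln.row(reference_id)
    ref_len = len(ref) - ref.count(GAP)
    if not 1 <= start <= end <= ref_len:
        raise ValueError(
            f"span {start}..{end} outside reference of length {ref_len}"
        )
    cols = []
    r = 0
    for i, c in enumerate(ref):
        if c != GAP:
            r += 1
            if start <= r <= end:
                cols.append(i)
            if r == end:
                break
    return cols


@dataclass
class ConsensusPattern:
    pattern: str
    rules: list[tuple[str, str, float]]  # (kind, residues, frequency) per column

    def __str__(self) -> str:
        return self.pattern


def consensus_pattern(
    prof: ConservationProfile,
    span_columns: list[int],
    t_fix: float = 0.7,
    t_class: float = 0.8,
    max_class: int = 3,
) -> ConsensusPattern:
    """Degenerate consensus over a span of columns.

    Per column: if the most frequent residue reaches t_fix, a fixed
    letter; else if the top 2..max_class residues jointly reach t_class,
    a bracketed class in descending-frequency order (alphabetical on
    exact ties); else X. Thresholds must satisfy 0.5 <= t_fix <= 1 and
    t_class >= t_fix.
    """
    if not span_columns:
        raise ValueError("empty span")
    if not (0.5 <= t_fix <= 1.0) or t_class < t_fix:
        raise ValueError("need 0.5 <= t_fix <= 1 and t_class >= t_fix")
    parts = []
    rules = []
    for col in span_columns:
        dist = prof.columns[col]
        if dist.n_residues == 0:
            parts.append("X")
            rules.append(("wildcard", "", 0.0))
            continue
        order = sorted(range(N_AA), key=lambda a: (-dist.p_a[a], AMINO_ACIDS[a]))
        top = order[0]
        if dist.p_a[top] >= t_fix:
            parts.append(AMINO_ACIDS[top])
            rules.append(("fixed", AMINO_ACIDS[top], float(dist.p_a[top])))
            continue
        made_class = False
        for size in range(2, max_class + 1):
            members = order[:size]
            joint = float(dist.p_a[members].sum())
            if joint >= t_class:
                letters = "".join(AMINO_ACIDS[a] for a in members)
                parts.append(f"[{letters}]")
                rules.append(("class", letters, joint))
                made_class = True
                break
        if not made_class:
            parts.append("X")
            rules.append(("wildcard", "", float(dist.p_a[top])))
    return ConsensusPattern(pattern="".join(parts), rules=rules)


def logo_matrix(prof: ConservationProfile, span_columns: list[int]) -> np.ndarray:
    """20 x span position probability matrix (columns sum to 1).

    All-gap columns are not admissible in a logo span.
    """
    cols = []
    for col in span_columns:
        d = prof.columns[col]
        if d.n_residues == 0:
            raise ValueError(f"all-gap column {col} in logo span")
        cols.append(d.p_a)
    return np.stack(cols, axis=1)


def profile_table(prof: ConservationProfile) -> pd.DataFrame:
    """Tabular profile: column, reference position, entropy, gap fraction,
    top residues — ready for TSV export."""
    rows = []
    low = prof.low_coverage()
    for i, d in enumerate(prof.columns):
        if d.n_residues:
            order = np.argsort(-d.p_a)[:3]
            top = ",".join(
                f"{AMINO_ACIDS[a]}:{d.p_a[a]:.3f}" for a in order if d.p_a[a] > 0
            )
        else:
            top = ""
        rows.append(
            {
                "column": i + 1,
                "ref_pos": int(prof.col_to_ref[i]) if prof.col_to_ref is not None else 0,
                "entropy": round(float(prof.entropy[i]), 6) if d.n_residues else np.nan,
                "gap_fraction": round(d.gap_fraction, 6),
                "low_coverage": bool(low[i]),
                "top_residues": top,
            }
        )
    return pd.DataFrame(rows)


def write_profile(prof: ConservationProfile, path: str | Path) -> None:
    profile_table(prof).to_csv(path, sep="\t", index=False)
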