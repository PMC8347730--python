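"""Column entropy, reference masking/mapping and consensus patterns."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crossmotif as cm
from crossmotif._seq import AMINO_ACIDS
from crossmotif.conserve import (
    ColumnDistribution,
    column_entropy,
    logo_matrix,
    profile,
    profile_table,
)
from crossmotif.famsim import parse_pattern
from crossmotif.msa import Alignment

PRINTED_PATTERN = "RXX[VL]XX[KR][KR]YXGC[LI][KR]X[LI]EISR[TS]"


def _dist(freqs: dict[str, float], n: int = 100) -> ColumnDistribution:
    p = np.zeros(20)
    for a, f in freqs.items():
        p[AMINO_ACIDS.index(a)] = f
    return ColumnDistribution(p_a=p, n_residues=n, gap_fraction=0.0)


class TestColumnEntropy:
    def test_single_residue_type_is_zero(self):
        assert column_entropy(_dist({"A": 1.0})) == 0.0

    def test_uniform_over_twenty_is_one(self):
        d = ColumnDistribution(p_a=np.full(20, 0.05), n_residues=100, gap_fraction=0.0)
        assert column_entropy(d) == pytest.approx(1.0, abs=1e-9)

    def test_two_residue_even_split_closed_form(self):
        # -2 * 0.5 * log20(0.5) = ln 2 / ln 20
        expected = math.log(2) / math.log(20)
        assert column_entropy(_dist({"A": 0.5, "C": 0.5})) == pytest.approx(
            expected, abs=1e-9
        )

    def test_all_gap_column_is_undefined_not_a_number(self):
        d = ColumnDistribution(p_a=np.zeros(20), n_residues=0, gap_fraction=1.0)
        with pytest.raises(ValueError):
            column_entropy(d)

    @settings(max_examples=300, deadline=None)
    @given(
        raw=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20)
    )
    def test_entropy_bounds_on_random_distributions(self, raw):
        p = np.zeros(20)
        p[: len(raw)] = raw
        p /= p.sum()
        d = ColumnDistribution(p_a=p, n_residues=50, gap_fraction=0.0)
        s = column_entropy(d)
        assert -1e-12 <= s <= 1.0 + 1e-12

    def test_spreading_mass_strictly_increases_entropy(self):
        one = column_entropy(_dist({"A": 1.0}))
        two = column_entropy(_dist({"A": 0.5, "C": 0.5}))
        assert two > one


class TestProfile:
    def test_identical_rows_fully_conserved(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["MKTAY"] * 3)
        prof = profile(aln)
        assert np.allclose(prof.entropy, 0.0)
        for col in prof.columns:
            assert col.p_a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_column_distributions_normalised(self, small_family):
        aln = cm.progressive_align(small_family)
        prof = profile(aln)
        for col in prof.columns:
            if col.n_residues:
                assert col.p_a.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(prof) == aln.n_columns

    def test_planted_motif_columns_less_variable_than_flanks(self):
        plant = cm.MotifPlant("MKTAYIAKQRQISFV", [0], occupancy=1.0,
                              degradation=0.0, anchored=True)
        cfg = cm.SimConfig(
            n_families=1, seqs_per_family=25, ancestor_length=120,
            substitution_rate=0.3, indel_rate=0.0, planted_motifs=[plant], seed=8,
        )
        fam = cm.simulate_families(cfg)[0]
        aln = cm.progressive_align(fam)
        prof = profile(aln)
        # all instances anchored at the same residue index, no indels:
        starts = {r.truth[0].start for r in fam}
        assert len(starts) == 1
        start = starts.pop()
        cols = cm.map_reference_span(aln, fam[0].id, start, start + 14)
        motif_mean = np.nanmean(prof.entropy[cols])
        flank = [i for i in range(aln.n_columns) if i not in cols]
        flank_mean = np.nanmean(prof.entropy[flank])
        assert motif_mean < flank_mean

    def test_all_gap_column_flagged_undefined(self):
        aln = Alignment(ids=["a", "b"], rows=["M-K", "M-K"])
        prof = profile(aln)
        assert not prof.defined[1]
        assert np.isnan(prof.entropy[1])
        assert prof.defined[0] and prof.defined[2]


class TestReferenceMapping:
    def test_mask_ungapped_reference_is_identity(self):
        aln = Alignment(ids=["r", "x"], rows=["MKTAY", "M-TAY"])
        masked = cm.mask_to_reference(aln, "r")
        assert masked.rows == aln.rows

    def test_mask_drops_reference_gap_columns(self):
        aln = Alignment(ids=["r", "x"], rows=["M--KTAY", "MAAKT-Y"])
        masked = cm.mask_to_reference(aln, "r")
        assert masked.n_columns == aln.n_columns - 2
        assert "-" not in masked.row("r")
        assert masked.row("x") == "MKT-Y"

    def test_unknown_reference_rejected(self):
        aln = Alignment(ids=["a"], rows=["MKT"])
        with pytest.raises(KeyError):
            cm.mask_to_reference(aln, "zz")

    def test_span_single_residue(self):
        aln = Alignment(ids=["r"], rows=["MKTAY"])
        assert cm.map_reference_span(aln, "r", 3, 3) == [2]

    def test_span_skips_leading_gap_columns(self):
        # reference starts with 3 gap columns: residues 1..5 sit in
        # alignment columns 4..8 (1-based), i.e. indices 3..7
        aln = Alignment(ids=["r", "x"], rows=["---MKTAY", "AAAMKTAY"])
        assert cm.map_reference_span(aln, "r", 1, 5) == [3, 4, 5, 6, 7]

    def test_span_length_is_end_minus_start_plus_one(self):
        aln = Alignment(ids=["r"], rows=["M-K-T-A-Y-W-C-D-E"])
        cols = cm.map_reference_span(aln, "r", 2, 6)
        assert len(cols) == 5

    def test_span_outside_reference_rejected(self):
        aln = Alignment(ids=["r"], rows=["MKTAY"])
        with pytest.raises(ValueError):
            cm.map_reference_span(aln, "r", 2, 9)

    def test_mask_then_extract_reproduces_reference_subsequence(self, small_family):
        aln = cm.progressive_align(small_family)
        ref = small_family[0].id
        cols = cm.map_reference_span(aln, ref, 5, 40)
        row = aln.row(ref)
        sub = "".join(row[i] for i in cols)
        assert sub == small_family[0].sequence[4:40]


def printed_pattern_alignment() -> Alignment:
    """50-row alignment whose column frequencies realise the degenerate
    laminin consensus: 90% fixed residues, 46/44 class splits, cycling
    filler elsewhere."""
    toks = parse_pattern(PRINTED_PATTERN)

    def fillers(exclude, n):
        pool = [a for a in AMINO_ACIDS if a not in exclude]
        return [pool[i % len(pool)] for i in range(n)]

    cols = []
    for kind, arg in toks:
        if kind == "fixed":
            cols.append([arg] * 45 + fillers(arg, 5))
        elif kind == "class":
            cols.append([arg[0]] * 23 + [arg[1]] * 22 + fillers(arg, 5))
        else:
            cols.append([AMINO_ACIDS[i % 20] for i in range(50)])
    rows = ["".join(cols[c][r] for c in range(len(toks))) for r in range(50)]
    return Alignment(ids=[f"s{i}" for i in range(50)], rows=rows)


class TestConsensusPattern:
    def test_fully_conserved_column_is_fixed_letter(self):
        aln = Alignment(ids=["a", "b"], rows=["R", "R"])
        prof = profile(aln)
        assert cm.consensus_pattern(prof, [0]).pattern == "R"

    def test_even_two_residue_split_becomes_class(self):
        # exact ties order alphabetically (the only row-order-invariant
        # deterministic rule); unequal splits order by frequency
        aln = Alignment(ids=[f"s{i}" for i in range(10)],
                        rows=["V"] * 5 + ["L"] * 5)
        prof = profile(aln)
        pat = cm.consensus_pattern(prof, [0], t_fix=0.7, t_class=0.8)
        assert pat.pattern == "[LV]"
        aln2 = Alignment(ids=[f"s{i}" for i in range(10)],
                         rows=["V"] * 6 + ["L"] * 4)
        assert cm.consensus_pattern(profile(aln2), [0]).pattern == "[VL]"

    def test_printed_laminin_pattern_reproduced(self):
        prof = profile(printed_pattern_alignment())
        pat = cm.consensus_pattern(prof, list(range(21)), t_fix=0.7, t_class=0.8)
        assert pat.pattern == PRINTED_PATTERN

    def test_invariant_to_row_order(self, rng):
        aln = printed_pattern_alignment()
        order = rng.permutation(len(aln.ids))
        shuffled = Alignment(
            ids=[aln.ids[i] for i in order], rows=[aln.rows[i] for i in order]
        )
        a = cm.consensus_pattern(profile(aln), list(range(21)))
        b = cm.consensus_pattern(profile(shuffled), list(range(21)))
        assert a.pattern == b.pattern

    def test_empty_span_rejected(self):
        prof = profile(Alignment(ids=["a"], rows=["MK"]))
        with pytest.raises(ValueError):
            cm.consensus_pattern(prof, [])

    def test_threshold_validation(self):
        prof = profile(Alignment(ids=["a"], rows=["MK"]))
        with pytest.raises(ValueError):
            cm.consensus_pattern(prof, [0], t_fix=0.3)
        with pytest.raises(ValueError):
            cm.consensus_pattern(prof, [0], t_fix=0.8, t_class=0.7)


class TestLogoMatrix:
    def test_one_hot_for_conserved_span(self):
        aln = Alignment(ids=["a", "b"], rows=["MK", "MK"])
        mat = logo_matrix(profile(aln), [0, 1])
        assert mat.shape == (20, 2)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)
        assert mat[AMINO_ACIDS.index("M"), 0] == 1.0

    def test_round_trips_profile_distributions(self, small_family):
        aln = cm.progressive_align(small_family)
        prof = profile(aln)
        span = [i for i in range(10) if prof.defined[i]]
        mat = logo_matrix(prof, span)
        for k, col in enumerate(span):
            assert np.array_equal(mat[:, k], prof.columns[col].p_a)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)


def test_profile_table_has_reference_coordinates(small_family):
    aln = cm.progressive_align(small_family)
    ref = small_family[0].id
    tab = profile_table(profile(aln, reference_id=ref))
    assert list(tab.columns) == [
        "column", "ref_pos", "entropy", "gap_fraction", "low_coverage", "top_residues",
    ]
    # reference positions are a 1..n enumeration over non-gap columns
    nonzero = tab.ref_pos[tab.ref_pos > 0]
    assert list(nonzero) == list(range(1, len(nonzero) + 1))
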