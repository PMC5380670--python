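import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from camfam import (
    GeneratorConfig,
    ProteinRecord,
    flag_z_position_substitutions,
    loop_frequency_table,
    make_cam_cohort,
    pair_ef_hands,
    scan_ef_hands,
)
from camfam.efhand import EFHandLoop

from .oracles import max_adjacent_pairing, scan_oracle


def make_loops(gaps, protein_id="p", template="DKDGDGTITTKE"):
    """Loops separated by the given linker gaps."""
    loops, start = [], 0
    for i in range(len(gaps) + 1):
        loops.append(EFHandLoop(protein_id, start, template))
        start += 12 + (gaps[i] if i < len(gaps) else 0)
    return loops


class TestScan:
    def test_single_canonical_loop(self):
        loops = scan_ef_hands(ProteinRecord("p", "AAADKDGDGTITTKEAAA"))
        assert [(l.start, l.residues, l.z_residue) for l in loops] == [
            (3, "DKDGDGTITTKE", "E")
        ]

    def test_too_short_protein_yields_nothing(self):
        assert scan_ef_hands(ProteinRecord("p", "AAAA")) == []

    def test_relaxed_mode_drops_minus_x_constraint(self):
        # Proline at position 9 violates the canonical -X constraint.
        seq = "DKDGDGTIPTKE"
        assert scan_ef_hands(ProteinRecord("p", seq), "canonical") == []
        assert len(scan_ef_hands(ProteinRecord("p", seq), "relaxed")) == 1

    def test_implanted_loops_recovered_exactly(self, cohort):
        records, truth = cohort
        for rec in records:
            found = [lp.start for lp in scan_ef_hands(rec)]
            assert found == truth[rec.id]["loop_starts"], rec.id

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=500))
    def test_scanner_matches_regex_oracle(self, seq):
        rec_starts = [lp.start for lp in scan_ef_hands(ProteinRecord("p", seq))] if seq else []
        assert rec_starts == scan_oracle(seq)
        if seq:
            relaxed = [lp.start for lp in scan_ef_hands(ProteinRecord("p", seq), "relaxed")]
            assert relaxed == scan_oracle(seq, "relaxed")


class TestPairing:
    def test_two_pair_architecture(self):
        paired = pair_ef_hands(make_loops([12, 60, 12]))
        assert [lp.paired_with for lp in paired] == [1, 0, 3, 2]

    def test_pair_plus_lone_hand(self):
        paired = pair_ef_hands(make_loops([12, 12]))
        assert [lp.paired_with for lp in paired] == [1, 0, None]
        assert not paired[2].is_paired

    def test_single_loop_stays_lone(self):
        (lone,) = pair_ef_hands(make_loops([]))
        assert lone.paired_with is None

    def test_unsorted_input_rejected(self):
        loops = list(reversed(make_loops([12, 12])))
        with pytest.raises(ValueError, match="sorted"):
            pair_ef_hands(loops)

    @given(st.lists(st.integers(min_value=0, max_value=60), max_size=6))
    def test_greedy_matches_bruteforce_maximum(self, gaps):
        paired = pair_ef_hands(make_loops(gaps))
        n_pairs = sum(1 for lp in paired if lp.is_paired) // 2
        assert n_pairs == max_adjacent_pairing(gaps, 8, 30)
        # no loop in two pairs: partner relation is an involution
        for i, lp in enumerate(paired):
            if lp.is_paired:
                assert paired[lp.paired_with].paired_with == i
        assert n_pairs <= len(paired) // 2


class TestFrequencyTable:
    def test_census_cohort_position_1_exclusively_aspartate(self, cohort):
        # The 19 CMLs of the default cohort carry 55 loops in total; +X is
        # an aspartate in every one of them.
        records, truth = cohort
        loops = [
            lp
            for rec in records
            if truth[rec.id]["family"] == "CML"
            for lp in scan_ef_hands(rec)
        ]
        table = loop_frequency_table(loops)
        assert table.n_loops == 55
        assert table.counts[1] == {"D": 55}
        assert table.consensus[0] == "D"
        assert table.counts[6] == {"G": 55}

    def test_single_loop_consensus_is_the_loop(self):
        table = loop_frequency_table([EFHandLoop("p", 0, "DKDGDGTITTKE")])
        assert table.consensus == list("DKDGDGTITTKE")

    def test_counts_match_naive_recount(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        loops = [
            EFHandLoop("p", 0, "".join(rng.choice(alphabet, size=12)))
            for _ in range(40)
        ]
        table = loop_frequency_table(loops)
        for pos in range(1, 13):
            naive = {}
            for lp in loops:
                aa = lp.residues[pos - 1]
                naive[aa] = naive.get(aa, 0) + 1
            assert table.counts[pos] == naive
            assert sum(table.counts[pos].values()) == table.n_loops

    def test_alternatives_bracketed_and_x_for_diverse_positions(self):
        loops = [EFHandLoop("p", 0, "DKDGDGTITTKE")] * 6 + [
            EFHandLoop("p", 0, "DKNGDGTITTKE")
        ] * 4
        table = loop_frequency_table(loops, alt_threshold=0.15)
        assert table.consensus[2] == "D[N]"
        # a position where every residue is rare renders 'x'
        diverse = [
            EFHandLoop("p", 0, "D" + aa + "DGDGTITTKE")
            for aa in "ACEFGHIKLMNPQRSTVWY"[:10]
        ]
        assert loop_frequency_table(diverse, alt_threshold=0.15).consensus[1] == "x"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            loop_frequency_table([])


class TestZSubstitutions:
    def test_glutamate_not_flagged_aspartate_flagged(self):
        loops = [
            EFHandLoop("p", 0, "DKDGDGTITTKE"),
            EFHandLoop("p", 30, "DKDGDGTITTKD"),
        ]
        assert flag_z_position_substitutions(loops) == [("p", 1)]

    def test_cohort_z_substitutions_match_truth(self, cohort):
        records, truth = cohort
        expected = [
            (rec.id, idx)
            for rec in records
            for idx in truth[rec.id]["z_sub_loops"]
        ]
        loops = [lp for rec in records for lp in scan_ef_hands(rec)]
        assert flag_z_position_substitutions(loops) == expected
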