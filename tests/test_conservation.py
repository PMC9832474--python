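"""Conservation grading, ConSurf parsing, and mutation suggestion logic."""

import numpy as np
import pytest

from tsscan.conservation import (
    AlignmentError,
    ConservationRecord,
    SubstitutionFilter,
    conservation_grades,
    henikoff_weights,
    map_columns,
    parse_consurf,
    read_msa,
    suggest_mutations,
)
from tsscan.geometry_analysis import ScanRecord
from tsscan.synthetic import make_toy_msa, write_msa


def _msa(plan, n_seqs=20, seed=0):
    return make_toy_msa(n_seqs, plan, seed=seed)


class TestReadMsa:
    def test_roundtrip_identity(self, tmp_path):
        aln = _msa(["high", "mid", "low"] * 3)
        write_msa(aln, tmp_path / "t.fasta")
        back = read_msa(tmp_path / "t.fasta")
        assert [str(r.seq) for r in back] == [str(r.seq) for r in aln]
        assert back[0].id == "query"

    def test_ragged_rows_rejected(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises(AlignmentError):
            read_msa(tmp_path / "bad.fasta")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "e.fasta").write_text("")
        with pytest.raises(AlignmentError, match="empty"):
            read_msa(tmp_path / "e.fasta")


class TestMapColumns:
    def test_gapless_query_identity(self):
        aln = _msa(["high"] * 6)
        assert map_columns(aln) == {i: i for i in range(1, 7)}

    def test_gapped_query_skips_columns(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">q\nA-C\n>h\nAAC\n")
        aln = read_msa(tmp_path / "g.fasta")
        assert map_columns(aln) == {1: 1, 3: 2}

    def test_matches_cursor_walk_on_random_gaps(self, tmp_path):
        rng = np.random.default_rng(5)
        query = "".join(rng.choice(["A", "C", "-"], size=40,
                                   p=[0.4, 0.4, 0.2]))
        (tmp_path / "r.fasta").write_text(f">q\n{query}\n>h\n{'A' * 40}\n")
        aln = read_msa(tmp_path / "r.fasta")
        expected, pos = {}, 0
        for col, ch in enumerate(query, start=1):
            if ch != "-":
                pos += 1
                expected[col] = pos
        assert map_columns(aln) == expected

    def test_missing_query_id(self):
        aln = _msa(["high"] * 3)
        with pytest.raises(AlignmentError, match="not in alignment"):
            map_columns(aln, query_id="nope")


class TestConservationGrades:
    def test_fully_conserved_column_grades_nine(self):
        grades = conservation_grades(_msa(["high"] * 4 + ["low"] * 8))
        assert all(g.grade == 9 for g in grades[:4])

    def test_uniform_column_grades_one(self):
        records = conservation_grades(_msa(["high"] * 8 + ["low"] * 4))
        lows = records[8:]
        assert min(g.grade for g in lows) == 1

    def test_all_identical_sequences_grade_nine_everywhere(self):
        records = conservation_grades(_msa(["high"] * 10))
        assert [g.grade for g in records] == [9] * 10

    def test_planted_ordering_recovered(self):
        plan = ["high"] * 4 + ["mid"] * 4 + ["low"] * 4
        records = conservation_grades(_msa(plan, n_seqs=30, seed=2))
        high = [records[i].grade for i in range(4)]
        mid = [records[i].grade for i in range(4, 8)]
        low = [records[i].grade for i in range(8, 12)]
        assert min(high) > max(mid) > min(mid) >= max(low) or \
            (min(high) > max(mid) and min(mid) > max(low))

    def test_invariant_under_sequence_permutation(self):
        aln = _msa(["high", "mid", "low"] * 4, n_seqs=25, seed=3)
        base = [g.grade for g in conservation_grades(aln)]
        rng = np.random.default_rng(0)
        others = list(aln[1:])
        rng.shuffle(others)
        from Bio.Align import MultipleSeqAlignment
        shuffled = MultipleSeqAlignment([aln[0]] + others)
        assert [g.grade for g in conservation_grades(shuffled)] == base

    def test_duplicated_sequences_absorbed_by_weights(self):
        aln = _msa(["high", "mid", "low"] * 3, n_seqs=20, seed=4)
        base = [g.grade for g in conservation_grades(aln)]
        from Bio.Align import MultipleSeqAlignment
        doubled = MultipleSeqAlignment(list(aln) + list(aln[1:]))
        dup = [g.grade for g in conservation_grades(doubled)]
        assert all(abs(a - b) <= 1 for a, b in zip(base, dup))

    def test_few_sequences_warn(self):
        with pytest.warns(UserWarning, match="non-query"):
            conservation_grades(_msa(["high"] * 3, n_seqs=4))

    def test_variability_excludes_query_residue(self):
        records = conservation_grades(_msa(["mid"] * 6, n_seqs=30, seed=1))
        for rec in records:
            assert rec.query_residue not in {aa for aa, _ in rec.variability}
            assert all(0 < f <= 1 for _, f in rec.variability)


class TestParseConsurf:
    def test_single_grade_row(self, tmp_path):
        (tmp_path / "g.txt").write_text("Asp87\t9\tGlu\n")
        rec, = parse_consurf(tmp_path / "g.txt")
        assert (rec.position, rec.grade) == (87, 9)
        assert rec.variant_residues() == {"E"}
        assert rec.query_residue == "D"

    def test_grade_range_and_variant_list(self, tmp_path):
        (tmp_path / "g.txt").write_text(
            "Asp214\t8–9\tVal, **Gly**, **Ala**, Glu, **Ser**\n")
        rec, = parse_consurf(tmp_path / "g.txt")
        assert rec.grade_range == (8, 9)
        assert rec.variant_residues() == {"V", "G", "A", "E", "S"}

    def test_empty_file_is_error(self, tmp_path):
        (tmp_path / "g.txt").write_text("")
        with pytest.raises(AlignmentError):
            parse_consurf(tmp_path / "g.txt")

    def test_malformed_row_is_error(self, tmp_path):
        (tmp_path / "g.txt").write_text("Asp87\tnine\tGlu\n")
        with pytest.raises(AlignmentError, match="malformed"):
            parse_consurf(tmp_path / "g.txt")


def _scan_record(number, name, **kw):
    defaults = dict(chem_class="POLAR", d_Op=5.0, d_SDBT=6.0, bulk=3)
    defaults.update(kw)
    return ScanRecord(residue_id=("A", number), residue_name=name,
                      **defaults)


class TestSuggestMutations:
    def test_variability_candidate_preferred(self):
        scan_records = [_scan_record(365, "GLU", ddE_ala=-1.5)]
        cons = [ConservationRecord(position=365, grade=9,
                                   variability=[("D", 0.2), ("Q", 0.1)],
                                   n_effective=30, query_residue="E")]
        out = suggest_mutations(scan_records, cons, mode="ALA_SCAN")
        via_var = [c for c in out if c.provenance == "variability"]
        assert [(c.wild_type, c.replacement) for c in via_var] == [("E", "Q")]
        assert all(c.replacement not in ("D", "E", "K", "R") for c in out)

    def test_probe_without_homologue_support_is_risky(self):
        scan_records = [_scan_record(132, "SER", ddE_probe_pos=-2.0)]
        cons = [ConservationRecord(position=132, grade=9,
                                   variability=[("A", 0.1)],
                                   n_effective=30, query_residue="S")]
        out = suggest_mutations(scan_records, cons, mode="PROBE")
        assert {c.replacement for c in out} == {"K", "R"}
        assert all(c.provenance == "risky" for c in out)

    def test_probe_with_homologue_support_not_risky(self):
        scan_records = [_scan_record(132, "SER", ddE_probe_pos=-2.0)]
        cons = [ConservationRecord(position=132, grade=9,
                                   variability=[("K", 0.1)],
                                   n_effective=30, query_residue="S")]
        out = suggest_mutations(scan_records, cons, mode="PROBE")
        by_repl = {c.replacement: c.provenance for c in out}
        assert by_repl["K"] == "variability"
        assert by_repl["R"] == "risky"

    def test_no_beneficial_residues_gives_empty_list(self):
        scan_records = [_scan_record(10, "GLU", ddE_ala=0.5,
                                     ddE_probe_pos=1.0, ddE_probe_neg=2.0)]
        assert suggest_mutations(scan_records, [], mode="ALA_SCAN") == []
        assert suggest_mutations(scan_records, [], mode="PROBE") == []

    def test_never_proposes_gly_or_pro(self):
        scan_records = [_scan_record(20, "ASP", ddE_ala=-3.0)]
        cons = [ConservationRecord(position=20, grade=8,
                                   variability=[("G", 0.3), ("P", 0.2),
                                                ("N", 0.1)],
                                   n_effective=30, query_residue="D")]
        out = suggest_mutations(scan_records, cons, mode="ALA_SCAN")
        assert out and all(c.replacement not in ("G", "P") for c in out)

    def test_excluded_positions_never_mutated(self):
        scan_records = [_scan_record(20, "ASP", ddE_ala=-3.0)]
        out = suggest_mutations(scan_records, [], mode="ALA_SCAN",
                                exclude_positions=[("A", 20)])
        assert out == []

    def test_blosum_filter_respects_min_score(self):
        scan_records = [_scan_record(20, "ASP", ddE_ala=-3.0)]
        strict = SubstitutionFilter(min_score=1)
        out = suggest_mutations(scan_records, [], strict, mode="ALA_SCAN")
        mat = strict.matrix
        assert out
        for c in out:
            assert mat["D", c.replacement] >= 1


def test_henikoff_weights_sum_to_one():
    aln = _msa(["high", "mid", "low"] * 2, n_seqs=15, seed=7)
    w = henikoff_weights(aln)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert (w > 0).all()
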