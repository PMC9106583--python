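"""Sequence, phosphosite-table and report I/O."""

import pandas as pd
import pytest

from chargeblocks import (
    AnnotatedSequence,
    PhosphositeTable,
    attach_sites,
    read_fasta,
    read_phosphosites,
    read_report,
    write_fasta,
    write_report,
)
from chargeblocks.sequences import (
    FastaParseError,
    MutationSpec,
    PhosphositeError,
    PointRule,
    RegionRule,
    SequenceError,
    read_mutation_spec,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKR\n")
        (rec,) = read_fasta(p)
        assert rec.id == "x" and rec.residues == "MKR" and len(rec) == 3
        assert rec.phosphosites == frozenset()

    def test_multi_record_order_preserved(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">b\nMK\n>a\nRR\n>c\nDD\n")
        assert [r.id for r in read_fasta(p)] == ["b", "a", "c"]

    def test_ambiguity_code_rejected_then_mapped(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMBR\n")
        with pytest.raises(FastaParseError, match="non-canonical"):
            read_fasta(p)
        (rec,) = read_fasta(p, permissive=True)
        assert rec.residues == "MXR"

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("MKR\n>x\nMK\n")
        with pytest.raises(FastaParseError, match=":1:"):
            read_fasta(p)

    def test_empty_record_is_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\n>y\nMK\n")
        with pytest.raises(FastaParseError, match="empty sequence"):
            read_fasta(p)

    def test_round_trip(self, tmp_path, random_sequences):
        seqs = random_sequences(5, seed=11)
        p = tmp_path / "rt.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [
            (s.id, s.residues) for s in seqs
        ]


class TestAnnotatedSequence:
    def test_site_at_non_st_rejected(self):
        with pytest.raises(PhosphositeError, match="not S/T"):
            AnnotatedSequence(id="x", residues="MGR", phosphosites={2})

    def test_site_at_non_st_override(self):
        seq = AnnotatedSequence(
            id="x", residues="MGR", phosphosites={2}, allow_non_st=True
        )
        assert seq.phosphosites == frozenset({2})

    def test_site_out_of_range(self):
        with pytest.raises(PhosphositeError, match="outside"):
            AnnotatedSequence(id="x", residues="MSR", phosphosites={9})

    def test_subsequence_remaps_sites(self):
        seq = AnnotatedSequence(id="x", residues="GGSKKTG", phosphosites={3, 6})
        sub = seq.subsequence(3, 6)
        assert sub.residues == "SKKT"
        assert sub.phosphosites == frozenset({1, 4})


class TestPhosphositeTable:
    def _table(self, rows):
        return PhosphositeTable.from_rows(rows)

    def test_nine_row_table(self, r12_sites):
        assert len(r12_sites) == 9

    def test_duplicate_rows_error(self):
        with pytest.raises(PhosphositeError, match="duplicate"):
            self._table([("p", 3, "S", "up"), ("p", 3, "S", "down")])

    def test_unknown_direction_error(self):
        with pytest.raises(PhosphositeError, match="direction"):
            self._table([("p", 3, "S", "sideways")])

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("protein_id\tposition\tresidue\tdirection\n")
        assert len(read_phosphosites(p)) == 0

    def test_read_comma_delimited(self, tmp_path):
        p = tmp_path / "sites.csv"
        p.write_text("protein_id,position,residue,direction\np,3,S,up\n")
        table = read_phosphosites(p)
        assert list(table.frame["position"]) == [3]


class TestAttachSites:
    def test_attach_nine_up_sites(self, r12_like, r12_sites):
        bare = r12_like.replace(phosphosites=frozenset(), phosphorylated=frozenset())
        seq = attach_sites(bare, r12_sites, direction="up")
        assert len(seq.phosphosites) == 9
        assert seq.phosphorylated == frozenset()

    def test_down_filter_on_up_only_table(self, r12_like, r12_sites):
        seq = attach_sites(r12_like, r12_sites, direction="down")
        assert seq.phosphosites == frozenset()

    def test_residue_mismatch_is_join_error(self):
        seq = AnnotatedSequence(id="p", residues="GGGSGG")
        table = PhosphositeTable.from_rows([("p", 2, "S", "up")])
        with pytest.raises(PhosphositeError, match="mismatch"):
            attach_sites(seq, table)

    def test_out_of_range_error(self):
        seq = AnnotatedSequence(id="p", residues="GGS")
        table = PhosphositeTable.from_rows([("p", 9, "S", "up")])
        with pytest.raises(PhosphositeError, match="outside"):
            attach_sites(seq, table)

    def test_idempotent(self, r12_like, r12_sites):
        once = attach_sites(r12_like, r12_sites)
        twice = attach_sites(once, r12_sites)
        assert once == twice


class TestReports:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"a": [1, 2], "b": ["x", "y"], "c": [0.5, 1.25]})
        p = tmp_path / "r.tsv"
        write_report(df, p)
        back = read_report(p)
        pd.testing.assert_frame_equal(df, back)

    def test_empty_dataframe_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report(pd.DataFrame(columns=["a", "b"]), p)
        assert p.read_text() == "a\tb\n"

    def test_float_precision_six_significant_digits(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report([{"v": 1.23456789012}], p)
        assert "1.23457" in p.read_text()


class TestMutationSpec:
    def test_conflicting_rules_rejected(self):
        seq = AnnotatedSequence(id="x", residues="GKGKGKGK")
        spec = MutationSpec(
            (RegionRule(1, 4, "KR_to_Q"), PointRule(2, "K", "Q"))
        )
        with pytest.raises(SequenceError, match="conflict"):
            spec.validate_against(seq)

    def test_point_rule_from_mismatch(self):
        seq = AnnotatedSequence(id="x", residues="GKG")
        with pytest.raises(SequenceError, match="expects"):
            MutationSpec((PointRule(1, "K", "Q"),)).validate_against(seq)

    def test_region_out_of_bounds(self):
        seq = AnnotatedSequence(id="x", residues="GKG")
        with pytest.raises(SequenceError, match="outside"):
            MutationSpec((RegionRule(1, 9, "KR_to_Q"),)).validate_against(seq)

    def test_unknown_kind(self):
        with pytest.raises(SequenceError, match="unknown region rule"):
            RegionRule(1, 2, "frobnicate")

    def test_read_spec_tsv(self, tmp_path):
        p = tmp_path / "spec.tsv"
        p.write_text(
            "kind\tstart\tend\tfrom\tto\tcount\n"
            "point\t2\t2\tK\tQ\t\n"
            "neutral_to_E\t5\t9\t\t\t3\n"
        )
        spec = read_mutation_spec(p)
        assert spec.rules[0] == PointRule(2, "K", "Q")
        assert spec.rules[1] == RegionRule(5, 9, "neutral_to_E", 3)
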