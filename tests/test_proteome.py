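"""Proteome model: FASTA/feature-table I/O, coordinate mapping, form enumeration."""

import random

import pytest

from unicity import (
    Block,
    Existence,
    Feature,
    FeatureKind,
    FormOptions,
    Isoform,
    ProteinEntry,
    Proteome,
    enumerate_sequence_forms,
    map_isoform_position_to_canonical,
    read_feature_table,
    read_proteome_fasta,
    write_feature_table,
    write_proteome_fasta,
)
from unicity.fixtures import ProteomeParams, generate_proteome
from unicity.proteome import (
    AlphabetError,
    BoundsError,
    ConsistencyError,
    FastaParseError,
    OrphanIsoformError,
    derive_deletion_alignment,
)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">sp|P00001|TEST1\nMKAAR\n")
        proteome = read_proteome_fasta(path)
        assert len(proteome) == 1
        assert proteome.get("P00001").canonical_seq == "MKAAR"

    def test_isoform_attaches_to_parent(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">sp|P00001|T\nMKAAR\n>P00001-2\nMKR\n")
        proteome = read_proteome_fasta(path)
        entry = proteome.get("P00001")
        assert [iso.iso_id for iso in entry.isoforms] == ["P00001-2"]
        assert entry.isoforms[0].seq == "MKR"
        assert entry.isoforms[0].alignment == []

    def test_orphan_isoform_rejected(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">P00009-2\nMKR\n")
        with pytest.raises(OrphanIsoformError):
            read_proteome_fasta(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = write(
            tmp_path, "p.fasta", ">sp|P00001|T\nMKAAR\n>oops_header\nMKR\n"
        )
        with pytest.raises(FastaParseError, match=r":3:"):
            read_proteome_fasta(path)

    def test_illegal_residue_names_position(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">sp|P00001|T\nMKXAR\n")
        with pytest.raises(AlphabetError, match="position 3"):
            read_proteome_fasta(path)

    def test_lowercase_and_terminator_normalized(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">sp|P00001|T\nmkaar*\n")
        assert read_proteome_fasta(path).get("P00001").canonical_seq == "MKAAR"

    def test_gene_and_existence_parsed(self, tmp_path):
        path = write(tmp_path, "p.fasta", ">sp|P00001|T GN=ABC1 PE=2\nMKAAR\n")
        entry = read_proteome_fasta(path).get("P00001")
        assert entry.gene_symbol == "ABC1"
        assert entry.existence is Existence.transcript_level


class TestFeatureTable:
    HEADER = "accession\ttarget_form\tkind\tbegin\tend\tpayload\n"

    def make_proteome(self):
        return Proteome(
            entries=[ProteinEntry(accession="P00001", canonical_seq="MKAAR")]
        )

    def test_transmem_attached(self, tmp_path):
        path = write(
            tmp_path, "f.tsv", self.HEADER + "P00001\tcanonical\tTRANSMEM\t2\t4\t-\n"
        )
        proteome, issues = read_feature_table(path, self.make_proteome())
        assert not issues
        (feat,) = proteome.get("P00001").features
        assert (feat.kind, feat.begin, feat.end) == (FeatureKind.TRANSMEM, 2, 4)

    def test_variant_consistent_accepted(self, tmp_path):
        path = write(
            tmp_path, "f.tsv", self.HEADER + "P00001\tcanonical\tVARIANT\t3\t3\tA>V\n"
        )
        proteome, issues = read_feature_table(path, self.make_proteome())
        assert not issues and len(proteome.get("P00001").features) == 1

    def test_variant_mismatch_skipped_and_reported(self, tmp_path):
        path = write(
            tmp_path, "f.tsv", self.HEADER + "P00001\tcanonical\tVARIANT\t3\t3\tG>V\n"
        )
        proteome, issues = read_feature_table(path, self.make_proteome())
        assert proteome.get("P00001").features == []
        assert len(issues) == 1 and "VARIANT" in issues[0].message

    def test_strict_mode_raises(self, tmp_path):
        path = write(
            tmp_path, "f.tsv", self.HEADER + "P00001\tcanonical\tVARIANT\t3\t3\tG>V\n"
        )
        with pytest.raises(ConsistencyError):
            read_feature_table(path, self.make_proteome(), strict=True)

    def test_unknown_accession_reported(self, tmp_path):
        path = write(
            tmp_path, "f.tsv", self.HEADER + "P99999\tcanonical\tCHAIN\t1\t3\t-\n"
        )
        _, issues = read_feature_table(path, self.make_proteome())
        assert len(issues) == 1 and "P99999" in issues[0].message


class TestIsoformMapping:
    def entry(self):
        # canonical M A K C D E F G H ; isoform deletes D-E (positions 5-6)
        return ProteinEntry(
            accession="P1",
            canonical_seq="MAKCDEFGH",
            isoforms=[
                Isoform(
                    iso_id="P1-2",
                    seq="MAKCFGH",
                    alignment=[Block(1, 1, 4), Block(7, 5, 3)],
                )
            ],
        )

    def test_mapping_across_deletion(self):
        assert map_isoform_position_to_canonical(self.entry(), "P1-2", 5) == 7

    def test_identity_at_block_start(self):
        assert map_isoform_position_to_canonical(self.entry(), "P1-2", 1) == 1

    def test_gap_position_maps_to_none(self):
        # isoform with an inserted W at position 5: canonical MAKCDEFGH
        entry = ProteinEntry(
            accession="P1",
            canonical_seq="MAKCDEFGH",
            isoforms=[
                Isoform(
                    iso_id="P1-2",
                    seq="MAKCWDEFGH",
                    alignment=[Block(1, 1, 4), Block(5, 6, 5)],
                )
            ],
        )
        assert map_isoform_position_to_canonical(entry, "P1-2", 5) is None
        assert map_isoform_position_to_canonical(entry, "P1-2", 6) == 5

    def test_out_of_range_raises(self):
        with pytest.raises(BoundsError):
            map_isoform_position_to_canonical(self.entry(), "P1-2", 99)

    def test_mapping_is_strictly_monotone(self):
        rng = random.Random(7)
        for _ in range(200):
            proteome, _ = generate_proteome(
                3, ProteomeParams(isoform_prob=1.0), seed=rng.randrange(2**31)
            )
            for entry in proteome.entries:
                for iso in entry.isoforms:
                    mapped = [
                        (p, map_isoform_position_to_canonical(entry, iso.iso_id, p))
                        for p in range(1, len(iso.seq) + 1)
                    ]
                    mapped = [(p, c) for p, c in mapped if c is not None]
                    for (p1, c1), (p2, c2) in zip(mapped, mapped[1:]):
                        assert p1 < p2 and c1 < c2

    def test_derive_deletion_alignment_matches_explicit(self):
        entry = self.entry()
        iso = entry.isoforms[0]
        assert derive_deletion_alignment(entry.canonical_seq, iso.seq) == iso.alignment


class TestEnumerateForms:
    def test_bare_entry_has_one_form(self):
        entry = ProteinEntry(accession="P1", canonical_seq="MKAAR")
        assert len(enumerate_sequence_forms(entry)) == 1

    def test_chain_and_variant_expansion(self, mkaar_entry):
        forms = enumerate_sequence_forms(mkaar_entry, FormOptions(apply_variants=True))
        assert [f.seq for f in forms] == ["MKAAR", "AAR", "MKAVR", "AVR"]
        assert [f.carries_variant for f in forms] == [False, False, True, True]

    def test_variants_off(self, mkaar_entry):
        forms = enumerate_sequence_forms(mkaar_entry, FormOptions(apply_variants=False))
        assert [f.seq for f in forms] == ["MKAAR", "AAR"]

    def test_form_count_law_on_random_fixtures(self):
        for seed in range(30):
            proteome, _ = generate_proteome(
                4,
                ProteomeParams(isoform_prob=0.7, variant_prob=0.8, chain_prob=0.8),
                seed=seed,
            )
            for entry in proteome.entries:
                processing = [
                    f
                    for f in entry.features
                    if f.kind.value in ("CHAIN", "PEPTIDE", "SIGNAL", "PROPEP")
                ]
                variants = [f for f in entry.features if f.kind is FeatureKind.VARIANT]
                expected = 1 + len(entry.isoforms) + len(processing)
                for var in variants:
                    containing = [
                        p for p in processing if p.begin <= var.begin <= p.end
                    ]
                    expected += 1 + len(containing)
                assert len(enumerate_sequence_forms(entry)) == expected

    def test_processed_form_remembers_parent_coordinates(self, mkaar_entry):
        chain = enumerate_sequence_forms(mkaar_entry)[1]
        assert (chain.base, chain.offset) == ("canonical", 3)
        assert chain.base_region(1, 3) == (3, 5)


class TestRoundTrip:
    def test_fasta_and_feature_table_round_trip(self, tmp_path):
        proteome, _ = generate_proteome(
            8,
            ProteomeParams(isoform_prob=0.8, variant_prob=0.8, tm_prob=0.8,
                           chain_prob=0.8),
            seed=11,
        )
        write_proteome_fasta(proteome, tmp_path / "p.fasta")
        write_feature_table(proteome, tmp_path / "f.tsv")
        again = read_proteome_fasta(tmp_path / "p.fasta",
                                    release_tag=proteome.release_tag)
        again, issues = read_feature_table(tmp_path / "f.tsv", again)
        assert not issues
        assert again.release_tag == proteome.release_tag
        for a, b in zip(proteome.entries, again.entries):
            assert a.accession == b.accession
            assert a.canonical_seq == b.canonical_seq
            assert a.gene_symbol == b.gene_symbol
            assert a.existence == b.existence
            assert [(i.iso_id, i.seq, i.alignment) for i in a.isoforms] == [
                (i.iso_id, i.seq, i.alignment) for i in b.isoforms
            ]
            assert [
                (f.kind, f.target_form, f.begin, f.end, f.payload) for f in a.features
            ] == [(f.kind, f.target_form, f.begin, f.end, f.payload) for f in b.features]
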