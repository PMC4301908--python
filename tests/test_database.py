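"""Tab-header FASTA dialect: write, read, export, aligned import."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbkit.database import (
    CustomDatabase,
    DatabaseRecord,
    export_sequences,
    import_aligned_fasta,
    read_database,
    write_database,
)
from arbkit.errors import (
    AlignmentShapeError,
    DatabaseError,
    DuplicateIdError,
    SchemaMismatchError,
)
from arbkit.fixtures import generate_database, random_schema
from arbkit.metalabels import MetaLabels


class TestWriteDatabase:
    def test_header_layout_bit_exact(self, schema3):
        db = CustomDatabase(schema3, [DatabaseRecord(
            "sq000001", ("AB123456", "Escherichia coli", "x"), "ACGT")])
        assert write_database(db) == \
            ">sq000001\tAB123456\tEscherichia coli\tx\nACGT\n"

    def test_empty_value_renders_as_empty_cell(self, small_db):
        text = write_database(small_db)
        assert "\n>sq000002\t\tBacillus sp.\tMFS transporter\n" in text

    def test_sequences_wrapped_at_70(self, small_db):
        lines = write_database(small_db).splitlines()
        seq_lines = [l for l in lines if not l.startswith(">")]
        assert max(len(l) for l in seq_lines) == 70
        assert any(len(l) < 70 for l in seq_lines)


class TestReadDatabase:
    def test_round_trip_small(self, small_db):
        assert read_database(write_database(small_db),
                             small_db.schema) == small_db

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_round_trip_randomized(self, seed):
        schema = random_schema(1 + seed % 8, seed=seed)
        db = generate_database(1 + seed % 30, schema, seed=seed,
                               gap_fraction=0.1 if seed % 3 == 0 else 0.0)
        assert read_database(write_database(db), schema) == db

    def test_any_wrapping_accepted(self, schema3):
        text = ">sq000001\ta\tb\tc\nACG\nT\nACGT\n"
        db = read_database(text, schema3)
        assert db.records[0].sequence == "ACGTACGT"

    def test_cell_count_mismatch_is_error(self, schema3):
        with pytest.raises(SchemaMismatchError) as exc:
            read_database(">sq000001\tonly_one\nACGT\n", schema3)
        assert "sq000001" in str(exc.value)

    def test_duplicate_uid_is_error(self, schema3):
        text = (">sq000001\ta\tb\tc\nACGT\n"
                ">sq000001\td\te\tf\nACGT\n")
        with pytest.raises(DuplicateIdError):
            read_database(text, schema3)

    def test_no_records_is_error(self, schema3):
        with pytest.raises(DatabaseError):
            read_database("\n\n", schema3)


class TestExportSequences:
    def test_headers_are_bare_uids_in_order(self, small_db):
        text = export_sequences(small_db)
        headers = [l for l in text.splitlines() if l.startswith(">")]
        assert headers == [">sq000001", ">sq000002", ">sq000003"]

    def test_strip_gaps(self, small_db):
        stripped = export_sequences(small_db, strip_gaps=True)
        assert "AC-GTA" not in stripped and "ACGTA" in stripped
        kept = export_sequences(small_db, strip_gaps=False)
        assert "AC-GTA" in kept


class TestImportAlignedFasta:
    ALIGNED = (">AAK53448\nMKT--AILAV\n"
               ">CAA36850\nMKTW-AILAV\n"
               ">EDL12345\nMK---AILAV\n")

    def test_gapped_records_with_minted_uids(self, schema3):
        db = import_aligned_fasta(self.ALIGNED, schema3)
        assert len(db) == 3
        assert db.records[0].sequence == "MKT--AILAV"
        assert all(rec.metadata == ("", "", "") for rec in db)
        assert db.manifest[db.records[0].uid] == "AAK53448"

    def test_metadata_source_by_accession(self, schema3):
        db = import_aligned_fasta(
            self.ALIGNED, schema3,
            metadata_source={"CAA36850": ["CAA36850", "E. coli", "MFS"]})
        assert db.records[1].metadata == ("CAA36850", "E. coli", "MFS")

    def test_ragged_alignment_is_error(self, schema3):
        with pytest.raises(AlignmentShapeError):
            import_aligned_fasta(">a\nMKTAILAVLL\n>b\nMKTAILAVL\n", schema3)

    def test_existing_uids_preserved(self, schema3):
        text = ">sq000007\nMKT--AILAV\n>xy000001\nMKTW-AILAV\n"
        db = import_aligned_fasta(text, schema3)
        assert db.uids() == ["sq000007", "xy000001"]

    def test_sequence_conserved_under_export_import(self, schema3):
        db = import_aligned_fasta(self.ALIGNED, schema3)
        exported = export_sequences(db, strip_gaps=True)
        for rec, line in zip(db, exported.splitlines()[1::2]):
            assert line == rec.ungapped()


class TestInvariants:
    def test_metadata_length_must_match_schema(self, schema3):
        with pytest.raises(SchemaMismatchError):
            CustomDatabase(schema3, [DatabaseRecord("sq000001", ("a",),
                                                    "ACGT")])

    def test_values_must_be_tab_free(self):
        with pytest.raises(DatabaseError):
            DatabaseRecord("sq000001", ("a\tb",), "ACGT")

    def test_sequence_must_be_non_empty(self):
        with pytest.raises(DatabaseError):
            DatabaseRecord("sq000001", ("a",), "")
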