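"""GenBank parsing, field resolution and unique-ID minting."""

import numpy as np
import pytest

from arbkit.errors import (
    EmptyInputError,
    IdCapacityError,
    MalformedRecordError,
    TruncationError,
)
from arbkit.extractor import (
    TaxdumpTaxonomy,
    build_records,
    extract_field,
    mint_unique_ids,
    parse_genbank,
    sanitize_value,
)
from arbkit.metalabels import MetaLabels

# Hand-written flat file (old-style VERSION line with a GI number).
# Expected values below were read off this text by hand.
HANDWRITTEN = """\
LOCUS       SYN00001                  40 bp    DNA     linear   BCT 01-JAN-2015
DEFINITION  Escherichia coli sugar transporter (abcT) gene, complete cds.
ACCESSION   AB000001
VERSION     AB000001.1  GI:10000001
KEYWORDS    .
SOURCE      Escherichia coli
  ORGANISM  Escherichia coli
            Bacteria; Proteobacteria.
REFERENCE   1
  AUTHORS   Doe,J. and Roe,R.
  TITLE     Synthetic record
  JOURNAL   J Synth Data 1 (1), 1-2 (2015)
FEATURES             Location/Qualifiers
     source          1..40
                     /organism="Escherichia coli"
                     /mol_type="genomic DNA"
                     /ph="7.2"
     CDS             1..40
                     /gene="abcT"
                     /locus_tag="SYN_0001"
                     /product="sugar transporter"
ORIGIN
        1 acgtacgtac acgtacgtac acgtacgtac acgtacgtac
//
"""


class TestParseGenbank:
    def test_handwritten_record_hand_parsed_values(self):
        (entry,) = parse_genbank(HANDWRITTEN)
        assert entry.locus == "SYN00001"
        assert entry.accession == "AB000001"
        assert entry.version == "AB000001.1"
        assert entry.gi == "10000001"
        assert entry.organism == "Escherichia coli"
        # semicolon-split, trailing period removed
        assert entry.taxonomy_lineage == ("Bacteria", "Proteobacteria")
        # ORIGIN digits/spaces stripped, uppercased
        assert entry.sequence == "ACGTACGTAC" * 4
        assert entry.source_qualifiers["ph"] == "7.2"
        assert entry.feature_qualifiers["product"] == "sugar transporter"
        assert entry.references[0]["authors"] == "Doe,J. and Roe,R."
        assert entry.references[0]["date"] == "2015"

    def test_multi_record_count_and_order(self, genbank_fixture):
        _, text, truth = genbank_fixture
        entries = parse_genbank(text)
        assert len(entries) == len(truth)
        assert [e.accession for e in entries] == \
            [gt["accession"] for gt in truth]

    def test_fixture_ground_truth_recovered_exactly(self, genbank_fixture):
        _, text, truth = genbank_fixture
        for entry, gt in zip(parse_genbank(text), truth):
            assert entry.sequence == gt["sequence"]
            for label, expected in gt.items():
                if label == "sequence":
                    continue
                assert extract_field(entry, label) == expected, label

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            parse_genbank("")
        with pytest.raises(EmptyInputError):
            parse_genbank("   \n\n")

    def test_truncated_record(self):
        with pytest.raises(TruncationError):
            parse_genbank(HANDWRITTEN + HANDWRITTEN.replace("//\n", ""))

    def test_record_without_origin_names_locus(self):
        text = HANDWRITTEN.split("ORIGIN")[0] + "//\n"
        with pytest.raises(MalformedRecordError) as exc:
            parse_genbank(text)
        assert "SYN00001" in str(exc.value)


class TestExtractField:
    def test_missing_environmental_field_is_empty(self):
        (entry,) = parse_genbank(HANDWRITTEN)
        assert extract_field(entry, "salinity") == ""
        assert extract_field(entry, "no_such_field") == ""

    def test_genus_is_first_binomial_token(self):
        (entry,) = parse_genbank(HANDWRITTEN)
        assert extract_field(entry, "genus") == "Escherichia"

    def test_phylum_positional_default(self):
        (entry,) = parse_genbank(HANDWRITTEN)
        assert extract_field(entry, "phylum") == "Proteobacteria"

    def test_values_are_tab_and_newline_free(self, genbank_fixture):
        _, text, truth = genbank_fixture
        labels = set(truth[0]) - {"sequence"}
        for entry in parse_genbank(text):
            for label in labels:
                value = extract_field(entry, label)
                assert "\t" not in value and "\n" not in value

    def test_taxdump_refines_ranks(self, tmp_path):
        (tmp_path / "names.dmp").write_text(
            "1\t|\tEscherichia\t|\t\t|\tscientific name\t|\n"
            "2\t|\tProteobacteria\t|\t\t|\tscientific name\t|\n"
            "3\t|\tBacteria\t|\t\t|\tscientific name\t|\n")
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t0\t|\tgenus\t|\n"
            "2\t|\t0\t|\tphylum\t|\n"
            "3\t|\t0\t|\tsuperkingdom\t|\n")
        tax = TaxdumpTaxonomy(tmp_path)
        (entry,) = parse_genbank(HANDWRITTEN)
        assert extract_field(entry, "genus", taxonomy=tax) == "Escherichia"
        assert extract_field(entry, "phylum", taxonomy=tax) == \
            "Proteobacteria"


class TestMintUniqueIds:
    def test_stated_scheme(self):
        assert mint_unique_ids(3, prefix="sq", start=1) == \
            ["sq000001", "sq000002", "sq000003"]

    def test_base36_against_numpy_oracle(self):
        # Independent base-36 rendering of the same counters.
        for start in (1, 35, 36, 36 * 36, 123456, 36 ** 6 - 1):
            (uid,) = mint_unique_ids(1, prefix="sq", start=start)
            assert uid == "sq" + np.base_repr(start, 36).lower().zfill(6)

    def test_all_distinct_at_scale(self):
        ids = mint_unique_ids(10_000, prefix="a", start=0)
        assert len(set(ids)) == 10_000
        assert all(len(i) <= 8 for i in ids)

    @pytest.mark.parametrize("kwargs", [
        dict(n=0),
        dict(n=2, start=36 ** 6 - 1),
        dict(n=1, prefix="ABC"),
        dict(n=1, prefix=""),
        dict(n=1, start=-1),
    ])
    def test_capacity_and_precondition_errors(self, kwargs):
        with pytest.raises(IdCapacityError):
            mint_unique_ids(**kwargs)


class TestBuildRecords:
    def test_shape_and_manifest(self, genbank_fixture, schema3):
        _, text, truth = genbank_fixture
        db = build_records(parse_genbank(text), schema3)
        assert len(db) == len(truth)
        assert all(len(rec.metadata) == 3 for rec in db)
        assert db.manifest[db.records[0].uid] == truth[0]["accession"]

    def test_tab_in_value_sanitized_to_space(self):
        assert sanitize_value("sugar\ttransporter") == "sugar transporter"
        assert sanitize_value("a\r\nb\t\tc") == "a b c"

    def test_deterministic_given_prefix_and_start(self, genbank_fixture,
                                                  schema3):
        _, text, _ = genbank_fixture
        entries = parse_genbank(text)
        db1 = build_records(entries, schema3, prefix="ab", start=5)
        db2 = build_records(entries, schema3, prefix="ab", start=5)
        assert db1 == db2
        assert db1.uids()[0] == "ab000005"

    def test_empty_entry_list_rejected(self, schema3):
        with pytest.raises(EmptyInputError):
            build_records([], schema3)

    def test_schema_order_defines_metadata_order(self, genbank_fixture):
        _, text, truth = genbank_fixture
        schema = MetaLabels(("gene_product", "accession"))
        db = build_records(parse_genbank(text), schema)
        for rec, gt in zip(db, truth):
            assert rec.metadata == (gt["gene_product"], gt["accession"])
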