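import pytest

from arbkit.database import CustomDatabase, DatabaseRecord
from arbkit.fixtures import FixtureSpec, generate_genbank
from arbkit.metalabels import MetaLabels


@pytest.fixture
def schema3() -> MetaLabels:
    """The worked-example schema: accession, species, gene product."""
    return MetaLabels(("accession", "species", "gene_product"))


@pytest.fixture
def small_db(schema3) -> CustomDatabase:
    return CustomDatabase(
        schema=schema3,
        records=[
            DatabaseRecord("sq000001",
                           ("AB123456", "Escherichia coli",
                            "sugar transporter"),
                           "ACGTACGT"),
            DatabaseRecord("sq000002",
                           ("", "Bacillus sp.", "MFS transporter"),
                           "AC-GTA"),
            DatabaseRecord("sq000003",
                           ("CD000001", "Aspergillus niger", ""),
                           "A" * 170),
        ],
    )


@pytest.fixture(scope="session")
def genbank_fixture():
    """A deterministic synthetic GenBank batch with its ground truth."""
    spec = FixtureSpec(n_records=12, seed=7)
    text, truth = generate_genbank(spec)
    return spec, text, truth
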