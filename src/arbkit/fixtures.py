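"""Deterministic synthetic fixtures with known ground truth.

Everything in this toolkit can be exercised offline: this module
generates syntactically valid multi-record GenBank flat files (emitted
through Biopython's own GenBank writer), random custom databases, and
random binary Newick trees — all pure functions of a seed, each paired
with its planted ground truth so the extraction pipeline can be checked
for exact value recovery without touching NCBI.

The default vocabularies echo the kind of data the pipeline was built
for: bacterial and fungal sugar-transporter genes with identification,
taxonomy, functional, environmental and publication metadata.  Records
deliberately include awkward cases — a tab inside a product qualifier,
environmental qualifiers present on only some records, lineages with a
trailing period — because each exercises a documented normalization
rule.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field as dc_field
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import Reference, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .database import CustomDatabase, DatabaseRecord
from .errors import FixtureError
from .extractor import sanitize_value
from .metalabels import MetaLabels

DEFAULT_LABELS = ("accession", "species", "gene_product", "ph", "date")

#: (organism, lineage) pool; lineage reads domain; phylum-position; ...
ORGANISMS = [
    ("Escherichia coli", ["Bacteria", "Pseudomonadota",
                          "Gammaproteobacteria", "Enterobacterales",
                          "Enterobacteriaceae", "Escherichia"]),
    ("Bacillus subtilis", ["Bacteria", "Bacillota", "Bacilli",
                           "Bacillales", "Bacillaceae", "Bacillus"]),
    ("Streptomyces coelicolor", ["Bacteria", "Actinomycetota",
                                 "Actinomycetes", "Kitasatosporales",
                                 "Streptomycetaceae", "Streptomyces"]),
    ("Pseudomonas putida", ["Bacteria", "Pseudomonadota",
                            "Gammaproteobacteria", "Pseudomonadales",
                            "Pseudomonadaceae", "Pseudomonas"]),
    ("Saccharomyces cerevisiae", ["Eukaryota", "Fungi", "Dikarya",
                                  "Ascomycota", "Saccharomycetes",
                                  "Saccharomycetales",
                                  "Saccharomycetaceae", "Saccharomyces"]),
    ("Aspergillus niger", ["Eukaryota", "Fungi", "Dikarya", "Ascomycota",
                           "Eurotiomycetes", "Eurotiales",
                           "Aspergillaceae", "Aspergillus"]),
]

PRODUCTS = [
    "sugar transporter",
    "MFS sugar:H+ symporter",
    "major facilitator superfamily transporter",
    "ABC transporter permease",
    "sugar\ttransporter",  # tab-damaged annotation, on purpose
    "glucose/galactose transporter",
]

GENES = ["sugE", "mfsT", "glcP", "xylE", "galP", "araE"]
AUTHORS = ["Doe,J. and Roe,R.", "Smith,A., Jones,B. and Lee,C.",
           "Garcia,M.", "Chen,W. and Patel,S."]
TITLES = [
    "Diversity of sugar transporter genes in environmental isolates",
    "Uptake systems for plant polymer degradation products",
    "Comparative analysis of carbohydrate transport proteins",
]


@dataclass
class FixtureSpec:
    """Parameters for one deterministic GenBank fixture batch."""

    n_records: int = 10
    schema: MetaLabels = dc_field(
        default_factory=lambda: MetaLabels(DEFAULT_LABELS))
    seed: int = 42
    seq_length_range: tuple[int, int] = (60, 240)
    value_vocab: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise FixtureError("n_records must be >= 1")
        lo, hi = self.seq_length_range
        if lo < 1 or lo > hi:
            raise FixtureError(
                f"bad seq_length_range: ({lo}, {hi})")


def _vocab(spec: FixtureSpec, key: str, default: list) -> list:
    if spec.value_vocab and key in spec.value_vocab:
        return list(spec.value_vocab[key])
    return default


def generate_genbank(spec: FixtureSpec) -> tuple[str, list[dict[str, str]]]:
    """Generate a multi-record GenBank flat file plus its ground truth.

    Returns ``(text, ground_truth)`` where ``ground_truth[i]`` maps
    every resolvable field name (plus ``sequence``) to the value the
    extraction pipeline should recover for record *i*.  Ground-truth
    values are computed here from the planted inputs by the documented
    normalization rules (tab→space sanitization, genus = first token of
    the binomial, phylum = second lineage entry, date = year in the
    journal citation), independently of the extractor.

    Output is a pure function of the spec: same spec, same bytes.
    """
    rng = random.Random(spec.seed)
    organisms = _vocab(spec, "organism", ORGANISMS)
    products = _vocab(spec, "gene_product", PRODUCTS)
    genes = _vocab(spec, "gene", GENES)
    authors = _vocab(spec, "author", AUTHORS)

    records: list[SeqRecord] = []
    truth: list[dict[str, str]] = []
    for i in range(spec.n_records):
        organism, lineage = organisms[rng.randrange(len(organisms))]
        product = products[rng.randrange(len(products))]
        gene = genes[rng.randrange(len(genes))]
        author = authors[rng.randrange(len(authors))]
        title = TITLES[rng.randrange(len(TITLES))]
        year = rng.randrange(2001, 2016)
        journal = (f"J Synth Data {rng.randrange(1, 30)} "
                   f"({rng.randrange(1, 13)}), "
                   f"{rng.randrange(1, 900)}-{rng.randrange(900, 1200)} "
                   f"({year})")
        length = rng.randrange(spec.seq_length_range[0],
                               spec.seq_length_range[1] + 1)
        seq = "".join(rng.choice("acgt") for _ in range(length))
        accession = f"SD{i + 1:06d}"
        locus = f"SYN{i + 1:05d}"
        locus_tag = f"SYN_{i + 1:04d}"
        definition = f"{organism} {product.replace(chr(9), ' ')} ({gene}) gene"

        source_quals = {
            "organism": [organism],
            "mol_type": ["genomic DNA"],
        }
        env: dict[str, str] = {}
        if rng.random() < 0.5:
            env["ph"] = f"{rng.uniform(3.0, 9.5):.1f}"
        if rng.random() < 0.4:
            env["salinity"] = f"{rng.uniform(0.1, 6.0):.1f}%"
        if rng.random() < 0.4:
            env["temperature"] = f"{rng.randrange(4, 75)}C"
        for key, value in env.items():
            source_quals[key] = [value]

        rec = SeqRecord(
            Seq(seq), id=f"{accession}.1", name=locus,
            description=definition)
        rec.annotations.update({
            "molecule_type": "DNA",
            "topology": "linear",
            "data_file_division": "BCT" if lineage[0] == "Bacteria" else "PLN",
            "date": "01-JAN-2015",
            "accessions": [accession],
            "organism": organism,
            "source": organism,
            "taxonomy": list(lineage),
        })
        ref = Reference()
        ref.authors = author
        ref.title = title
        ref.journal = journal
        rec.annotations["references"] = [ref]
        rec.features = [
            SeqFeature(SimpleLocation(0, length), type="source",
                       qualifiers=source_quals),
            SeqFeature(SimpleLocation(0, length), type="CDS",
                       qualifiers={"gene": [gene],
                                   "locus_tag": [locus_tag],
                                   "product": [product]}),
        ]
        records.append(rec)

        truth.append({
            "locus": locus,
            "accession": accession,
            "version": f"{accession}.1",
            "gi": "",
            "definition": definition,
            "organism": organism,
            "species": organism,
            "genus": organism.split()[0],
            "phylum": lineage[1],
            "gene_product": sanitize_value(product),
            "product": sanitize_value(product),
            "gene": gene,
            "locus_tag": locus_tag,
            "date": str(year),
            "author": author,
            "journal": journal,
            "title": title,
            "ph": env.get("ph", ""),
            "salinity": env.get("salinity", ""),
            "temperature": env.get("temperature", ""),
            "sequence": seq.upper(),
        })

    out = StringIO()
    SeqIO.write(records, out, "genbank")
    return out.getvalue(), truth


def generate_tree(uids: list[str], seed: int = 0) -> str:
    """Random binary Newick tree over *uids* with positive branch lengths.

    Deterministic per ``(uids, seed)``; the leaf set equals the input
    ID set.  Branch lengths are uniform on (0.01, 0.5), printed with 4
    decimals.
    """
    if len(uids) < 2:
        raise FixtureError("need at least 2 IDs to build a tree")
    rng = random.Random(seed)

    def bl() -> str:
        return f"{rng.uniform(0.01, 0.5):.4f}"

    nodes = list(uids)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a}:{bl()},{b}:{bl()})")
    return nodes[0] + ";\n"


_VALUE_CHARS = string.ascii_letters + string.digits + " .,;:()'/%+-_"


def random_schema(n_fields: int, seed: int = 0) -> MetaLabels:
    """Random valid meta-labels schema of *n_fields* distinct labels."""
    rng = random.Random(seed)
    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < n_fields:
        head = rng.choice(string.ascii_lowercase)
        tail = "".join(rng.choice(string.ascii_lowercase + string.digits + "_")
                       for _ in range(rng.randrange(2, 10)))
        label = head + tail
        if label not in seen:
            seen.add(label)
            labels.append(label)
    return MetaLabels(tuple(labels))


def generate_database(
    n_records: int,
    schema: MetaLabels,
    seed: int = 0,
    prefix: str = "sq",
    seq_length_range: tuple[int, int] = (20, 120),
    gap_fraction: float = 0.0,
) -> CustomDatabase:
    """Random valid :class:`CustomDatabase` for round-trip testing.

    Metadata values draw from a printable alphabet including spaces and
    punctuation (never tabs/newlines) and are empty ~10% of the time;
    sequences are random nucleotides, optionally interspersed with
    alignment gaps at rate *gap_fraction*.
    """
    from .extractor import mint_unique_ids

    rng = random.Random(seed)
    uids = mint_unique_ids(n_records, prefix=prefix, start=1)
    records = []
    for uid in uids:
        values = []
        for _ in schema:
            if rng.random() < 0.1:
                values.append("")
            else:
                n = rng.randrange(1, 25)
                values.append("".join(
                    rng.choice(_VALUE_CHARS) for _ in range(n)).strip()
                    or "x")
        length = rng.randrange(*seq_length_range)
        seq = "".join(
            "-" if rng.random() < gap_fraction else rng.choice("ACGT")
            for _ in range(length))
        if not seq.strip("-"):
            seq = "A" + seq[1:]
        records.append(DatabaseRecord(uid=uid, metadata=tuple(values),
                                      sequence=seq))
    return CustomDatabase(schema=schema, records=records)


def estimate_pairwise_alignments(
    n: int, t_per_pair: float | None = None
) -> dict[str, float | int | None]:
    """Cost of an all-against-all progressive alignment: n(n-1)/2 pairs.

    This is the arithmetic that motivates outsourcing in the first
    place: pairwise-alignment counts grow quadratically, so a corpus of
    ~10k sequences needs tens of millions of pairwise alignments.
    Returns the exact integer pair count and, when a per-pair time is
    given, the total seconds and days it implies.
    """
    if n < 1:
        raise FixtureError("n must be >= 1")
    if t_per_pair is not None and t_per_pair < 0:
        raise FixtureError("t_per_pair must be >= 0")
    n_pairs = n * (n - 1) // 2
    result: dict[str, float | int | None] = {"n_pairs": n_pairs}
    if t_per_pair is None:
        result["total_seconds"] = None
    else:
        result["total_seconds"] = n_pairs * t_per_pair
        result["total_days"] = n_pairs * t_per_pair / 86400.0
    return result


def make_fixture_dir(outdir: str | Path, n_records: int = 8,
                     seed: int = 42, prefix: str = "sq") -> Path:
    """Write a self-contained demo directory exercising the pipeline.

    Produces the meta-labels file, a synthetic GenBank flat file with
    its ground truth, and the expected downstream artifacts (custom
    database, bare-ID FASTA, import filter, a random tree over the
    minted IDs, and the ID→accession manifest).  Used by the tutorial
    walk-through and as CLI demo input.
    """
    from .database import export_sequences, write_database
    from .extractor import build_records, parse_genbank
    from .iftgen import (DEFAULT_FILTER_FILENAME, build_import_filter,
                         render_ift)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = FixtureSpec(n_records=n_records, seed=seed)
    (outdir / "meta_labels.txt").write_text(
        "# Metadata schema for the demo database\n"
        "Accession\nSpecies\nGene Product\npH\nDate\n")
    gb_text, truth = generate_genbank(spec)
    (outdir / "records.gb").write_text(gb_text)
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1) + "\n")

    db = build_records(parse_genbank(gb_text), spec.schema, prefix=prefix)
    (outdir / "database.fasta").write_text(write_database(db))
    (outdir / "sequences.fasta").write_text(export_sequences(db))
    (outdir / DEFAULT_FILTER_FILENAME).write_text(
        render_ift(build_import_filter(spec.schema)))
    (outdir / "tree.nwk").write_text(generate_tree(db.uids(), seed=seed))
    (outdir / "manifest.tsv").write_text("".join(
        f"{uid}\t{acc}\n" for uid, acc in db.manifest.items()))
    return outdir
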