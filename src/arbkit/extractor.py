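"""GenBank extraction, field resolution and unique-ID minting.

Parses multi-record GenBank flat files (via Biopython), resolves the
metadata fields a meta-labels schema asks for, mints a short stable
unique ID per entry, and assembles the custom database.  The unique ID
is the backbone of the whole pipeline: it travels in the bare-ID FASTA
to external alignment/tree services and comes back as the Newick leaf
name, so it must be short (ARB keys entries by a short ``name`` field),
deterministic and unique within a database.

Field resolution is deliberately total: a label that cannot be resolved
yields the empty string, never an error, because realistic schemas
include environmental fields (pH, salinity, ...) that most GenBank
records simply lack.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .database import CustomDatabase, DatabaseRecord
from .errors import (
    EmptyInputError,
    IdCapacityError,
    MalformedRecordError,
    TruncationError,
)
from .metalabels import MetaLabels, normalize_label

_SEQ_RE = re.compile(r"^[A-Za-z]+$")
_YEAR_RE = re.compile(r"\((\d{4})\)\s*$")
_WS = re.compile(r"[\t\r\n]+")

#: Base-36 digit alphabet for ID counters.
BASE36 = "0123456789abcdefghijklmnopqrstuvwxyz"
ID_COUNTER_WIDTH = 6
ID_MAX_TOTAL_LEN = 8


def sanitize_value(value: str) -> str:
    """Collapse tabs/newlines to single spaces and trim.

    The database header is tab-delimited, so stored values must be
    tab-free; this mapping is lossy by design.
    """
    return _WS.sub(" ", value).strip()


@dataclass
class GenBankEntry:
    """One parsed GenBank record, reduced to what the pipeline uses."""

    locus: str
    accession: str
    version: str
    definition: str
    organism: str
    taxonomy_lineage: tuple[str, ...]
    sequence: str
    gi: str = ""
    source_qualifiers: dict[str, str] = dc_field(default_factory=dict)
    feature_qualifiers: dict[str, str] = dc_field(default_factory=dict)
    references: list[dict[str, str]] = dc_field(default_factory=list)


def _check_flatfile_shape(text: str) -> list[str]:
    """Split raw flat-file text into record chunks, validating framing."""
    stripped = text.strip()
    if not stripped:
        raise EmptyInputError("no GenBank records in input")
    chunks: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.rstrip() == "//":
            chunks.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(line.strip() for line in current):
        locus = _locus_of("\n".join(current))
        raise TruncationError(
            f"record {locus!r} is not terminated by '//' (truncated input?)")
    if not chunks:
        raise EmptyInputError("no GenBank records in input")
    return chunks


def _locus_of(chunk: str) -> str:
    for line in chunk.splitlines():
        if line.startswith("LOCUS"):
            parts = line.split()
            if len(parts) > 1:
                return parts[1]
    return "<unknown>"


def _qualifier_map(features, *, source: bool) -> dict[str, str]:
    """Pool qualifiers, first occurrence wins, keys normalized."""
    out: dict[str, str] = {}
    for feat in features:
        if (feat.type == "source") != source:
            continue
        for key, values in feat.qualifiers.items():
            try:
                nkey = normalize_label(key)
            except Exception:
                continue
            if nkey not in out and values:
                out[nkey] = str(values[0])
    return out


def _references_of(record) -> list[dict[str, str]]:
    refs = []
    for ref in record.annotations.get("references", []):
        journal = ref.journal or ""
        m = _YEAR_RE.search(journal)
        refs.append({
            "authors": ref.authors or "",
            "title": ref.title or "",
            "journal": journal,
            "date": m.group(1) if m else "",
        })
    return refs


def parse_genbank(text: str) -> list[GenBankEntry]:
    """Parse concatenated GenBank flat-file records.

    Returns one :class:`GenBankEntry` per record in file order.  The
    ORIGIN block's coordinates and spacing are stripped (sequence is
    uppercased); the ORGANISM lineage is split on semicolons with the
    trailing period removed.

    Raises
    ------
    EmptyInputError
        No records at all.
    TruncationError
        Trailing record content without a ``//`` terminator.
    MalformedRecordError
        A record without a usable ORIGIN/sequence block (locus named).
    """
    chunks = _check_flatfile_shape(text)
    for chunk in chunks:
        if not any(line.startswith("ORIGIN") for line in chunk.splitlines()):
            raise MalformedRecordError(_locus_of(chunk), "no ORIGIN block")

    entries: list[GenBankEntry] = []
    for record in SeqIO.parse(StringIO(text), "genbank"):
        try:
            seq = str(record.seq).upper()
        except UndefinedSequenceError:
            raise MalformedRecordError(record.name, "sequence is undefined")
        if not seq:
            raise MalformedRecordError(record.name, "empty sequence")
        if not _SEQ_RE.match(seq):
            raise MalformedRecordError(
                record.name, "sequence contains non-IUPAC characters")
        lineage = tuple(
            t.strip().rstrip(".")
            for t in record.annotations.get("taxonomy", [])
            if t.strip()
        )
        accessions = record.annotations.get("accessions") or [record.name]
        entries.append(GenBankEntry(
            locus=record.name,
            accession=accessions[0],
            version=record.id,
            gi=str(record.annotations.get("gi", "") or ""),
            definition=record.description,
            organism=record.annotations.get("organism", ""),
            taxonomy_lineage=lineage,
            source_qualifiers=_qualifier_map(record.features, source=True),
            feature_qualifiers=_qualifier_map(record.features, source=False),
            references=_references_of(record),
            sequence=seq,
        ))
    if not entries:
        raise EmptyInputError("no GenBank records in input")
    return entries


class TaxdumpTaxonomy:
    """Optional offline NCBI taxdump (names.dmp/nodes.dmp) rank lookup.

    When present, maps scientific names to ranks so ``genus`` and
    ``phylum`` come from the taxonomy rather than from positional
    heuristics on the record's lineage.  Entirely optional; nothing in
    the pipeline requires it.
    """

    def __init__(self, directory: str | Path):
        directory = Path(directory)
        name_to_taxid: dict[str, str] = {}
        for line in (directory / "names.dmp").read_text().splitlines():
            parts = [p.strip() for p in line.split("|")]
            if len(parts) >= 4 and parts[3] == "scientific name":
                name_to_taxid.setdefault(parts[1], parts[0])
        taxid_to_rank: dict[str, str] = {}
        for line in (directory / "nodes.dmp").read_text().splitlines():
            parts = [p.strip() for p in line.split("|")]
            if len(parts) >= 3:
                taxid_to_rank[parts[0]] = parts[2]
        self._rank = {
            name: taxid_to_rank.get(taxid, "")
            for name, taxid in name_to_taxid.items()
        }

    def rank_of(self, name: str) -> str:
        return self._rank.get(name, "")

    def find_rank(self, names, rank: str) -> str:
        for name in names:
            if self.rank_of(name) == rank:
                return name
        return ""


def extract_field(
    entry: GenBankEntry,
    label: str,
    taxonomy: TaxdumpTaxonomy | None = None,
) -> str:
    """Resolve one normalized field name against a GenBank entry.

    Lookup chain: built-in resolvers for well-known labels, then the
    source feature's qualifiers (which cover environmental fields such
    as ``ph`` or ``salinity`` when a submitter recorded them), then
    qualifiers pooled over the remaining features, then the empty
    string.  Never raises; the result is always tab- and newline-free.
    """
    value = _resolve(entry, label, taxonomy)
    return sanitize_value(value)


def _resolve(entry, label, taxonomy):
    first_ref = entry.references[0] if entry.references else {}
    builtin = {
        "accession": lambda: entry.accession,
        "gi": lambda: entry.gi,
        "version": lambda: entry.version,
        "definition": lambda: entry.definition,
        "locus": lambda: entry.locus,
        "organism": lambda: entry.organism,
        "species": lambda: entry.organism,
        "source_organism": lambda: entry.organism,
        "genus": lambda: _genus(entry, taxonomy),
        "phylum": lambda: _phylum(entry, taxonomy),
        "gene_product": lambda: entry.feature_qualifiers.get("product", ""),
        "product": lambda: entry.feature_qualifiers.get("product", ""),
        "date": lambda: first_ref.get("date", ""),
        "author": lambda: first_ref.get("authors", ""),
        "authors": lambda: first_ref.get("authors", ""),
        "journal": lambda: first_ref.get("journal", ""),
        "title": lambda: first_ref.get("title", ""),
    }
    if label in builtin:
        value = builtin[label]()
        if value:
            return value
    if label in entry.source_qualifiers:
        return entry.source_qualifiers[label]
    if label in entry.feature_qualifiers:
        return entry.feature_qualifiers[label]
    return ""


def _genus(entry: GenBankEntry, taxonomy) -> str:
    if taxonomy is not None:
        hit = taxonomy.find_rank(
            (*reversed(entry.taxonomy_lineage), entry.organism.split()[0]
             if entry.organism else ""), "genus")
        if hit:
            return hit
    # First whitespace token of the binomial.
    return entry.organism.split()[0] if entry.organism else ""


def _phylum(entry: GenBankEntry, taxonomy) -> str:
    if taxonomy is not None:
        hit = taxonomy.find_rank(entry.taxonomy_lineage, "phylum")
        if hit:
            return hit
    # Positional default: lineages read domain; phylum; class; ...
    if len(entry.taxonomy_lineage) >= 2:
        return entry.taxonomy_lineage[1]
    return ""


def mint_unique_ids(n: int, prefix: str = "sq", start: int = 1) -> list[str]:
    """Mint *n* deterministic unique IDs: prefix + 6-digit base-36 counter.

    IDs are at most 8 characters — ARB keys species by a short ``name``
    field — and a run is a pure function of ``(prefix, start)``, so
    re-extraction reproduces identical databases.

    Raises
    ------
    IdCapacityError
        If the counter would exceed base-36 width 6 (36**6 IDs/prefix),
        or the prefix is not 1-2 lowercase alphanumeric characters.
    """
    if n < 1:
        raise IdCapacityError(f"need at least one ID, got n={n}")
    if not re.match(r"^[a-z0-9]{1,2}$", prefix):
        raise IdCapacityError(
            f"prefix {prefix!r} must be 1-2 lowercase alphanumeric characters")
    if start < 0:
        raise IdCapacityError(f"start counter must be >= 0, got {start}")
    if start + n - 1 >= 36 ** ID_COUNTER_WIDTH:
        raise IdCapacityError(
            f"counter overflow: {start + n - 1} >= 36^{ID_COUNTER_WIDTH}")
    return [prefix + _base36(start + i) for i in range(n)]


def _base36(value: int) -> str:
    digits = []
    for _ in range(ID_COUNTER_WIDTH):
        value, rem = divmod(value, 36)
        digits.append(BASE36[rem])
    return "".join(reversed(digits))


def build_records(
    entries: list[GenBankEntry],
    schema: MetaLabels,
    prefix: str = "sq",
    start: int = 1,
    taxonomy: TaxdumpTaxonomy | None = None,
) -> CustomDatabase:
    """Assemble a :class:`CustomDatabase` from parsed GenBank entries.

    Unique IDs are minted in entry order; each metadata row is resolved
    via :func:`extract_field` in schema order.  The database manifest
    keeps the ID → accession correspondence so metadata can be added to
    existing entries later.
    """
    if not entries:
        raise EmptyInputError("no entries to build records from")
    uids = mint_unique_ids(len(entries), prefix=prefix, start=start)
    records = [
        DatabaseRecord(
            uid=uid,
            metadata=tuple(
                extract_field(entry, label, taxonomy) for label in schema),
            sequence=entry.sequence,
        )
        for uid, entry in zip(uids, entries)
    ]
    manifest = {uid: e.accession for uid, e in zip(uids, entries)}
    return CustomDatabase(schema=schema, records=records, manifest=manifest)
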