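"""The custom FASTA database and its bare-ID export.

The custom database is a FASTA dialect in which each entry is a
TAB-delimited header line — unique ID first, then one cell per
meta-label, in schema order — followed by the sequence::

    >sq000001<TAB>AB123456<TAB>Escherichia coli
    ACGT...

This file is what the generated ARB import filter parses, so the writer
here and the filter in :mod:`arbkit.iftgen` define the dialect jointly.
The bare-ID export (:func:`export_sequences`) strips every header down
to the unique ID; that file is what gets shipped to external alignment
and tree-building services, and the ID is the join key that later links
their Newick output back to the metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from io import StringIO

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DatabaseError,
    DuplicateIdError,
    SchemaMismatchError,
)
from .metalabels import MetaLabels

#: Column width used when wrapping sequences on output.  Reading accepts
#: any wrapping (including none).
WRAP = 70

#: Gap characters accepted in aligned sequences ('-' is emitted; '.' is
#: accepted because ARB uses dot-style terminal gaps).
GAP_CHARS = "-."

_FORBIDDEN = re.compile(r"[\t\r\n]")
_UID_RE = re.compile(r"^[a-z0-9]{1,2}[0-9a-z]{6}$")


def is_uid(label: str) -> bool:
    """True if *label* has the shape of a minted unique ID."""
    return bool(_UID_RE.match(label))


@dataclass(frozen=True)
class DatabaseRecord:
    """One sequence with its unique ID and ordered metadata values.

    ``metadata`` is parallel to the schema's labels.  Values are plain
    strings (empty string = missing) and must be free of tab/newline so
    the tab-delimited header stays parseable.  ``sequence`` may carry
    alignment gaps.
    """

    uid: str
    metadata: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        if not self.uid or _FORBIDDEN.search(self.uid):
            raise DatabaseError(f"invalid unique ID: {self.uid!r}")
        for value in self.metadata:
            if _FORBIDDEN.search(value):
                raise DatabaseError(
                    f"metadata value for {self.uid!r} contains tab/newline: "
                    f"{value!r}")
        if not self.sequence:
            raise DatabaseError(f"record {self.uid!r} has an empty sequence")

    def ungapped(self) -> str:
        return re.sub(f"[{re.escape(GAP_CHARS)}]", "", self.sequence)


@dataclass
class CustomDatabase:
    """Ordered record collection bound to one meta-labels schema.

    ``manifest`` retains the unique-ID → source-accession (or source
    header) correspondence so metadata can be added to existing entries
    later without re-extraction.
    """

    schema: MetaLabels
    records: list[DatabaseRecord]
    manifest: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.uid in seen:
                raise DuplicateIdError(rec.uid)
            seen.add(rec.uid)
            if len(rec.metadata) != len(self.schema):
                raise SchemaMismatchError(
                    f"record {rec.uid!r} has {len(rec.metadata)} metadata "
                    f"values but the schema defines {len(self.schema)} fields")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def uids(self) -> list[str]:
        return [rec.uid for rec in self.records]

    def __getitem__(self, uid: str) -> DatabaseRecord:
        for rec in self.records:
            if rec.uid == uid:
                return rec
        raise KeyError(uid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CustomDatabase):
            return NotImplemented
        return self.schema == other.schema and self.records == other.records


def _wrap(seq: str) -> str:
    return "\n".join(seq[i:i + WRAP] for i in range(0, len(seq), WRAP))


def write_database(db: CustomDatabase) -> str:
    """Serialize *db* in the tab-delimited-header FASTA dialect.

    One header line per record — ``>`` + uid + one TAB-prefixed cell per
    metadata value — followed by the sequence wrapped at 70 columns.
    Record order is preserved; output ends with a newline.
    """
    out: list[str] = []
    for rec in db.records:
        out.append(">" + "\t".join((rec.uid, *rec.metadata)))
        out.append(_wrap(rec.sequence))
    return "\n".join(out) + "\n"


def read_database(text: str, schema: MetaLabels) -> CustomDatabase:
    """Parse tab-header FASTA content back into a :class:`CustomDatabase`.

    Exact inverse of :func:`write_database` on its image; any sequence
    wrapping is accepted.  The header cell count must equal
    ``1 + len(schema)`` — a mismatch means the meta-labels file and the
    database have drifted apart, which is precisely the failure the
    unique-ID system exists to surface, so it is an error rather than
    silently padded.

    Raises
    ------
    SchemaMismatchError
        Header with the wrong number of cells (reports uid and line).
    DuplicateIdError
        Two records share a unique ID.
    """
    records: list[DatabaseRecord] = []
    header_cells: list[str] | None = None
    seq_parts: list[str] = []
    header_line = 0

    def flush() -> None:
        if header_cells is None:
            return
        records.append(DatabaseRecord(
            uid=header_cells[0],
            metadata=tuple(header_cells[1:]),
            sequence="".join(seq_parts),
        ))

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            flush()
            cells = line[1:].split("\t")
            if len(cells) != 1 + len(schema):
                raise SchemaMismatchError(
                    f"line {lineno}: header for {cells[0]!r} has "
                    f"{len(cells)} cells, expected {1 + len(schema)} "
                    f"(uid + {len(schema)} metadata fields)")
            header_cells = cells
            header_line = lineno
            seq_parts = []
        elif line.strip():
            if header_cells is None:
                raise DatabaseError(
                    f"line {lineno}: sequence data before any header")
            seq_parts.append(line.strip())
    flush()
    if not records:
        raise DatabaseError("no records found in database content")
    del header_line
    return CustomDatabase(schema=schema, records=records)


def export_sequences(db: CustomDatabase, strip_gaps: bool = True) -> str:
    """Render the bare-ID FASTA used for outsourced computation.

    Headers carry only the unique ID, in database order, so external
    alignment/tree services see nothing but the join key.  With
    ``strip_gaps`` (the default) alignment gaps are removed, yielding
    raw sequences ready for re-alignment; without it, columns are kept
    verbatim.
    """
    out: list[str] = []
    for rec in db.records:
        out.append(">" + rec.uid)
        out.append(_wrap(rec.ungapped() if strip_gaps else rec.sequence))
    return "\n".join(out) + "\n"


def import_aligned_fasta(
    text: str,
    schema: MetaLabels,
    metadata_source: dict[str, list[str] | tuple[str, ...]] | None = None,
    prefix: str = "sq",
    start: int = 1,
) -> CustomDatabase:
    """Build a database from a pre-aligned plain FASTA (e.g. a curated
    CDD family export).

    All sequences must share one aligned length; gaps are retained.
    Headers that already look like minted unique IDs are kept (so a tree
    built earlier from those IDs stays linked); other headers get fresh
    IDs.  ``metadata_source`` maps header (first whitespace-delimited
    token) to a metadata row in schema order; unmatched headers get an
    all-empty row.

    Raises
    ------
    AlignmentShapeError
        Sequences of differing lengths.
    """
    from .extractor import mint_unique_ids, sanitize_value

    entries = [
        (rec.id, str(rec.seq))
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]
    if not entries:
        raise DatabaseError("no sequences found in aligned FASTA input")
    lengths = {len(seq) for _, seq in entries}
    if len(lengths) > 1:
        raise AlignmentShapeError(
            f"aligned sequences have differing lengths: {sorted(lengths)}")

    metadata_source = metadata_source or {}
    taken = {header for header, _ in entries if is_uid(header)}
    # Mint enough to survive collisions with preserved IDs.
    fresh = iter(mint_unique_ids(2 * len(entries), prefix=prefix, start=start))

    records: list[DatabaseRecord] = []
    manifest: dict[str, str] = {}
    for header, seq in entries:
        if is_uid(header):
            uid = header
        else:
            uid = next(fresh)
            while uid in taken:
                uid = next(fresh)
            taken.add(uid)
        row = metadata_source.get(header)
        if row is None:
            values = ("",) * len(schema)
        elif len(row) != len(schema):
            raise SchemaMismatchError(
                f"metadata row for {header!r} has {len(row)} values, "
                f"expected {len(schema)}")
        else:
            values = tuple(sanitize_value(v) for v in row)
        records.append(DatabaseRecord(uid=uid, metadata=values, sequence=seq))
        manifest[uid] = header
    return CustomDatabase(schema=schema, records=records, manifest=manifest)
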