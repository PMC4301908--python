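"""ARB import-filter generation and a reference interpreter.

ARB ingests flat files through declarative ``.ift`` import filters:
directive scripts that say how to detect the format, where each entry
begins and ends, and which pieces of the entry land in which database
fields.  Given a meta-labels schema, :func:`build_import_filter`
produces the filter for the matching tab-header custom database — one
rule per header column, with column 0 written to ARB's reserved
``name`` key (the unique ID) and column *i* written to label *i - 1*.

The emitted dialect is a conservative subset of ARB's directives
(``AUTODETECT``/``KEYWIDTH``/``BEGIN``/``MATCH``/``WRITE``/
``SEQUENCEAFTER``/``SEQUENCEEND``/``END``) with one extraction
directive, ``TABCOLUMN n``: split the matched header on tabs and take
the zero-based cell *n*.  ARB's general search-replace micro-syntax is
intentionally abstracted behind this single directive so the filter's
semantics stay fully defined by the reference interpreter
(:func:`apply_filter`), which makes correctness testable without an ARB
installation.

Patterns use shell-style globs (``*`` wildcard), matching ARB's
convention in ``AUTODETECT`` lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fnmatch import fnmatchcase

from .errors import FilterApplyError, FilterError, FilterParseError
from .metalabels import LABEL_RE, MetaLabels

DEFAULT_FILTER_FILENAME = "custom_import_filter.ift"
ARB_IMPORT_DIR_HINT = "/arb/lib/import/"

#: ARB's reserved per-entry key; tree import matches leaf names against it.
NAME_FIELD = "name"


@dataclass(frozen=True)
class FieldRule:
    """One header column bound to one ARB field."""

    match_pattern: str
    column: int
    target_field: str

    def __post_init__(self) -> None:
        if self.column < 0:
            raise FilterError(f"negative column index: {self.column}")
        if self.target_field != NAME_FIELD and not LABEL_RE.match(
                self.target_field):
            raise FilterError(
                f"unsafe WRITE target field: {self.target_field!r}")


@dataclass(frozen=True)
class ImportFilter:
    """Structured ``.ift`` filter; rendering is bit-reproducible."""

    rules: tuple[FieldRule, ...]
    autodetect_pattern: str = ">*"
    keywidth: int = 8
    begin_pattern: str = ">*"
    sequence_after: str = ""
    sequence_end: str = ">*"
    end_pattern: str = "*"

    def __post_init__(self) -> None:
        if not self.rules:
            raise FilterError("an import filter needs at least one rule")
        if self.rules[0].target_field != NAME_FIELD:
            raise FilterError(
                f"first rule must write the reserved {NAME_FIELD!r} field")
        columns = [r.column for r in self.rules]
        targets = [r.target_field for r in self.rules]
        if len(set(columns)) != len(columns):
            raise FilterError("duplicate column index across rules")
        if len(set(targets)) != len(targets):
            raise FilterError("duplicate WRITE target across rules")


def build_import_filter(schema: MetaLabels) -> ImportFilter:
    """Build the import filter matching a schema's custom database.

    Exactly ``1 + len(schema)`` rules: column 0 → ``name`` (the unique
    ID), column *i* → ``schema.labels[i-1]``.  Pure function of the
    schema: equal schemas render byte-identically.
    """
    rules = [FieldRule(match_pattern=">*", column=0, target_field=NAME_FIELD)]
    for i, label in enumerate(schema, start=1):
        rules.append(FieldRule(match_pattern=">*", column=i,
                               target_field=label))
    return ImportFilter(rules=tuple(rules))


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _unquote(s: str) -> str:
    s = s.strip()
    if not (len(s) >= 2 and s[0] == '"' and s[-1] == '"'):
        raise FilterParseError(f"expected quoted string, got {s!r}")
    return re.sub(r'\\(["\\])', r"\1", s[1:-1])


def render_ift(flt: ImportFilter) -> str:
    """Render the filter as ``.ift`` text (install under /arb/lib/import/)."""
    lines = [
        "# Generated ARB import filter for a tab-delimited custom database.",
        f"# Install into the ARB import filter directory {ARB_IMPORT_DIR_HINT}",
        f"AUTODETECT\t{_quote(flt.autodetect_pattern)}",
        f"KEYWIDTH\t{flt.keywidth}",
        "",
        f"BEGIN\t{_quote(flt.begin_pattern)}",
        "",
    ]
    for rule in flt.rules:
        lines.append(f"MATCH\t{_quote(rule.match_pattern)}")
        lines.append(f"\tTABCOLUMN\t{rule.column}")
        lines.append(f"\tWRITE\t{_quote(rule.target_field)}")
        lines.append("")
    lines.append(f"SEQUENCEAFTER\t{_quote(flt.sequence_after)}")
    lines.append(f"SEQUENCEEND\t{_quote(flt.sequence_end)}")
    lines.append(f"END\t{_quote(flt.end_pattern)}")
    return "\n".join(lines) + "\n"


def parse_ift(text: str) -> ImportFilter:
    """Parse rendered ``.ift`` text back into an :class:`ImportFilter`.

    Inverse of :func:`render_ift` on its image (comments are ignored).
    """
    simple: dict[str, str] = {}
    keywidth = 8
    rules: list[FieldRule] = []
    pending: dict[str, object] = {}

    def close_match() -> None:
        if not pending:
            return
        missing = {"match", "column", "write"} - set(pending)
        if missing:
            raise FilterParseError(f"incomplete MATCH block: missing {missing}")
        rules.append(FieldRule(
            match_pattern=pending["match"],
            column=pending["column"],
            target_field=pending["write"],
        ))
        pending.clear()

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            directive, arg = line.split(None, 1)
        except ValueError:
            raise FilterParseError(f"malformed directive line: {raw!r}")
        if directive == "MATCH":
            close_match()
            pending["match"] = _unquote(arg)
        elif directive == "TABCOLUMN":
            pending["column"] = int(arg)
        elif directive == "WRITE":
            pending["write"] = _unquote(arg)
        elif directive == "KEYWIDTH":
            keywidth = int(arg)
        elif directive in ("AUTODETECT", "BEGIN", "SEQUENCEAFTER",
                           "SEQUENCEEND", "END"):
            simple[directive] = _unquote(arg)
        else:
            raise FilterParseError(f"unknown directive: {directive!r}")
    close_match()
    if not rules:
        raise FilterParseError("no MATCH blocks found")
    return ImportFilter(
        rules=tuple(rules),
        autodetect_pattern=simple.get("AUTODETECT", ">*"),
        keywidth=keywidth,
        begin_pattern=simple.get("BEGIN", ">*"),
        sequence_after=simple.get("SEQUENCEAFTER", ""),
        sequence_end=simple.get("SEQUENCEEND", ">*"),
        end_pattern=simple.get("END", "*"),
    )


@dataclass
class ImportedEntry:
    """One entry as ARB would import it: bound fields plus sequence."""

    fields: dict[str, str]
    sequence: str


def _literal_prefix(pattern: str) -> str:
    return pattern.split("*", 1)[0]


def apply_filter(flt: ImportFilter, text: str) -> list[ImportedEntry]:
    """Reference interpreter: run the filter over custom-database text.

    Entries start at lines matching ``BEGIN``; the header payload is the
    line minus the pattern's literal prefix, split on tabs for
    ``TABCOLUMN`` extraction; subsequent lines up to ``SEQUENCEEND`` are
    collected (whitespace-stripped) as the sequence.  This is the
    behavioral contract the emitted filters are tested against in place
    of a live ARB importer.

    Raises
    ------
    FilterApplyError
        An entry header with fewer tab cells than the largest rule
        column index (the offending entry is named).
    """
    prefix = _literal_prefix(flt.begin_pattern)
    max_col = max(rule.column for rule in flt.rules)
    entries: list[ImportedEntry] = []
    header: str | None = None
    header_line = 0
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        cells = header.split("\t")
        if len(cells) <= max_col:
            raise FilterApplyError(
                f"entry {cells[0]!r} (line {header_line}) has {len(cells)} "
                f"tab cells but the filter extracts column {max_col}")
        fields = {
            rule.target_field: cells[rule.column] for rule in flt.rules
        }
        entries.append(ImportedEntry(fields=fields,
                                     sequence="".join(seq_parts)))

    for lineno, line in enumerate(text.splitlines(), start=1):
        if fnmatchcase(line, flt.begin_pattern):
            flush()
            header = line[len(prefix):] if line.startswith(prefix) else line
            header_line = lineno
            seq_parts = []
        elif header is not None and fnmatchcase(line, flt.sequence_end):
            flush()
            header = None
            seq_parts = []
        elif header is not None and line.strip():
            seq_parts.append(line.strip())
    flush()
    return entries
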