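"""Exception hierarchy.

Every error raised by this package derives from :class:`ArbkitError`, so
callers (including the CLI) can distinguish validation failures from
genuine bugs or I/O problems with a single ``except`` clause.
"""

from __future__ import annotations


class ArbkitError(Exception):
    """Base class for all toolkit errors (CLI exit code 2)."""


# --- meta-labels schema -------------------------------------------------

class SchemaError(ArbkitError):
    """Problem with the meta-labels schema."""


class SchemaEmptyError(SchemaError):
    """Meta-labels file contained no usable field names."""


class DuplicateLabelError(SchemaError):
    def __init__(self, label: str):
        self.label = label
        super().__init__(f"duplicate meta-label after normalization: {label!r}")


class IllegalLabelError(SchemaError):
    def __init__(self, raw: str, reason: str = ""):
        self.raw = raw
        msg = f"illegal meta-label {raw!r}"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


# --- GenBank extraction -------------------------------------------------

class GenBankError(ArbkitError):
    """Problem parsing GenBank flat-file input."""


class EmptyInputError(GenBankError):
    pass


class TruncationError(GenBankError):
    """Input ended without the record terminator ``//``."""


class MalformedRecordError(GenBankError):
    def __init__(self, locus: str, reason: str):
        self.locus = locus
        super().__init__(f"malformed GenBank record {locus!r}: {reason}")


class IdCapacityError(ArbkitError):
    """Requested more unique IDs than the counter width can hold."""


# --- custom database ----------------------------------------------------

class DatabaseError(ArbkitError):
    pass


class SchemaMismatchError(DatabaseError):
    """Header cell count disagrees with the bound schema."""


class DuplicateIdError(DatabaseError):
    def __init__(self, uid: str):
        self.uid = uid
        super().__init__(f"duplicate unique ID: {uid!r}")


class AlignmentShapeError(DatabaseError):
    """Aligned FASTA sequences do not all share one length."""


# --- import filter ------------------------------------------------------

class FilterError(ArbkitError):
    pass


class FilterParseError(FilterError):
    pass


class FilterApplyError(FilterError):
    """An entry could not be imported under the filter's rules."""


# --- tree linkage -------------------------------------------------------

class TreeError(ArbkitError):
    pass


class NewickParseError(TreeError):
    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class TreeLinkError(TreeError):
    def __init__(self, unmatched: list[str]):
        self.unmatched = list(unmatched)
        shown = ", ".join(repr(u) for u in self.unmatched)
        super().__init__(f"tree leaves not found in database: {shown}")


class DuplicateLeafError(TreeError):
    def __init__(self, label: str):
        self.label = label
        super().__init__(f"duplicate leaf label in tree: {label!r}")


class UnknownFieldError(TreeError):
    def __init__(self, field: str):
        self.field = field
        super().__init__(f"unknown relabel field: {field!r}")


class FixtureError(ArbkitError):
    pass
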