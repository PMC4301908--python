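"""Meta-labels: the user-authored metadata schema.

A meta-labels file lists one metadata field name per line (e.g.
``Accession``, ``Species``, ``Gene Product``).  The parsed, normalized
list is the single schema shared by every downstream artifact: it fixes
the column order of the custom database header, the field order of the
generated ARB import filter, and the vocabulary available for tree
relabeling.  The unique-ID column is *not* part of the schema; it is the
implicit first column of every header.

Field names are normalized to ARB-safe identifiers (lowercase letters,
digits and underscores, starting with a letter) because ARB stores
per-entry data under short machine-readable keys.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import DuplicateLabelError, IllegalLabelError, SchemaEmptyError

#: Pattern every normalized label must match (ARB-safe identifier).
LABEL_RE = re.compile(r"^[a-z][a-z0-9_]*$")

_SEPARATOR_RUN = re.compile(r"[\s\-]+")


def normalize_label(raw: str) -> str:
    """Normalize a display name to an ARB-safe field identifier.

    Lowercases, trims, and collapses every run of whitespace and/or
    hyphens to a single underscore, so ``"Gene Product"`` becomes
    ``"gene_product"``.  The mapping is idempotent.

    Raises
    ------
    IllegalLabelError
        If the input is empty after trimming or the normalized form is
        not a legal identifier (e.g. starts with a digit).
    """
    trimmed = raw.strip()
    if not trimmed:
        raise IllegalLabelError(raw, "empty after trimming")
    label = _SEPARATOR_RUN.sub("_", trimmed.lower())
    if not LABEL_RE.match(label):
        raise IllegalLabelError(raw, f"normalizes to {label!r}, which is not "
                                "a valid field name (lowercase letters, digits "
                                "and '_', starting with a letter)")
    return label


@dataclass(frozen=True)
class MetaLabels:
    """Ordered, validated metadata schema.

    ``labels`` are normalized field names in file order; order defines
    the header-column order of the custom database and the field order
    of the import filter.  ``source_path`` is provenance only and does
    not participate in equality.
    """

    labels: tuple[str, ...]
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.labels:
            raise SchemaEmptyError("meta-labels schema is empty")
        seen: set[str] = set()
        for label in self.labels:
            if not LABEL_RE.match(label):
                raise IllegalLabelError(label, "not normalized")
            if label in seen:
                raise DuplicateLabelError(label)
            seen.add(label)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def render(self) -> str:
        """Serialize as a meta-labels file (one label per line)."""
        return "".join(f"{label}\n" for label in self.labels)


def parse_meta_labels(text: str, source_path: str | None = None) -> MetaLabels:
    """Parse meta-labels file content into a validated schema.

    One candidate field name per line; blank lines and ``#`` comment
    lines are ignored.  Each name is normalized before validation, so
    ``"Gene Product"`` and ``"gene_product"`` denote the same field
    (and therefore collide as duplicates).

    Raises
    ------
    SchemaEmptyError
        No usable lines.
    DuplicateLabelError
        Two lines normalize to the same field name.
    IllegalLabelError
        A line normalizes to an illegal identifier.
    """
    labels: list[str] = []
    seen: set[str] = set()
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        label = normalize_label(stripped)
        if label in seen:
            raise DuplicateLabelError(label)
        seen.add(label)
        labels.append(label)
    if not labels:
        raise SchemaEmptyError("meta-labels file defines no fields")
    return MetaLabels(tuple(labels), source_path=source_path)
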