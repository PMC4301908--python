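"""Linking externally built Newick trees back to the custom database.

Trees come back from outsourced alignment/tree services with leaf names
equal to the unique IDs that were exported in the bare-ID FASTA.  This
module validates that linkage (every leaf must resolve to exactly one
database record), and supports the exploratory relabeling workflow:
replacing leaf IDs with any combination of metadata fields — e.g. the
protein product — while leaving topology and branch lengths untouched.
The uid-labeled tree remains the canonical artifact for ARB's tree
import; relabeled trees are for viewers.

Parsing and serialization are delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .database import CustomDatabase, DatabaseRecord
from .errors import (
    DuplicateLeafError,
    NewickParseError,
    TreeLinkError,
    UnknownFieldError,
)

#: Pseudo-field usable in relabeling: the leaf's unique ID itself.
UID_FIELD = "uid"


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick statement into a dendropy tree.

    Quoted labels are unescaped per Newick rules and underscores in
    unquoted labels are preserved verbatim (no space substitution).
    Balance and termination problems are reported with a character
    offset into the stripped statement.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input", offset=0)
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'",
                               offset=len(stripped))
    _check_balance(stripped)
    try:
        return dendropy.Tree.get(
            data=stripped, schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.\
            NewickReaderDuplicateTaxonError as exc:
        raise DuplicateLeafError(str(exc)) from exc
    except Exception as exc:  # dendropy error types vary by failure mode
        raise NewickParseError(f"Newick parse failed: {exc}") from exc


def _check_balance(text: str) -> None:
    depth = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced ')'", offset=offset)
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at statement end", offset=len(text))


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single Newick statement.

    Labels containing Newick-special characters (spaces, parentheses,
    commas, colons, quotes) are quoted; branch lengths and internal
    labels are preserved.  ``parse_newick(write_newick(t))`` is label-
    and topology-identical to ``t``.
    """
    return tree.as_string(schema="newick", suppress_rooting=True,
                          preserve_spaces=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def topology_signature(tree: dendropy.Tree):
    """Label-free structural fingerprint (nested sorted tuples).

    Two trees have equal signatures iff their shapes (and branch
    lengths) match, regardless of how the leaves are named — the
    invariant relabeling must preserve.
    """
    def sig(node):
        if node.is_leaf():
            return ((), node.edge.length)
        children = sorted((sig(c) for c in node.child_nodes()), key=repr)
        return (tuple(children), node.edge.length)
    return sig(tree.seed_node)


@dataclass
class LinkedTree:
    """A parsed tree whose leaves are bound to database records."""

    tree: dendropy.Tree
    db: CustomDatabase
    binding: dict[str, DatabaseRecord]
    n_leaves: int
    n_matched: int


def link_tree(tree: dendropy.Tree, db: CustomDatabase) -> LinkedTree:
    """Bind every leaf to its database record by exact unique-ID match.

    The tree may cover a strict subset of the database (pruning before
    tree building is normal), but a leaf absent from the database
    severs the sequence/metadata linkage and is an error — every
    unmatched label is listed.

    Raises
    ------
    DuplicateLeafError
        Two leaves share a label.
    TreeLinkError
        One or more leaves not present in the database.
    """
    labels = leaf_labels(tree)
    seen: set[str] = set()
    for label in labels:
        if label in seen:
            raise DuplicateLeafError(label)
        seen.add(label)
    by_uid = {rec.uid: rec for rec in db.records}
    unmatched = [label for label in labels if label not in by_uid]
    if unmatched:
        raise TreeLinkError(unmatched)
    binding = {label: by_uid[label] for label in labels}
    return LinkedTree(tree=tree, db=db, binding=binding,
                      n_leaves=len(labels), n_matched=len(labels))


def relabel_leaves(
    lt: LinkedTree,
    fields: list[str],
    sep: str = " ",
    keep_uid: bool = False,
) -> dendropy.Tree:
    """Return a copy of the tree with leaves renamed from metadata.

    Each leaf label becomes the requested field values joined by *sep*
    (the pseudo-field ``uid`` names the unique ID itself); with
    ``keep_uid`` the ID is prepended, which restores label uniqueness
    when metadata values repeat.  Topology, branch lengths and internal
    labels are untouched; the input tree is not modified.

    Raises
    ------
    UnknownFieldError
        A requested field is neither ``uid`` nor a schema label.
    """
    schema = lt.db.schema
    for field in fields:
        if field != UID_FIELD and field not in schema:
            raise UnknownFieldError(field)

    # Deep copy via serialization so the caller's tree is untouched.
    out = parse_newick(write_newick(lt.tree))
    for leaf in out.leaf_node_iter():
        uid = leaf.taxon.label
        record = lt.binding[uid]
        parts = [
            uid if field == UID_FIELD
            else record.metadata[schema.index(field)]
            for field in fields
        ]
        if keep_uid:
            parts.insert(0, uid)
        leaf.taxon.label = sep.join(parts)
    return out
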