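# Methods

## The pipeline model

`arbkit` treats a phylogenetics project as a set of artifacts tied
together by two invariants:

* **One schema.** The meta-labels file is the only declaration of what
  metadata exists. Its parsed, normalized form (`MetaLabels`) defines the
  column order of the custom database header, the field order of the ARB
  import filter, and the vocabulary for tree relabeling. Any disagreement
  between schema and database is surfaced as an error, never papered over.
* **One join key.** Every record gets a unique ID at extraction time; the
  ID is the FASTA header sent to external services and the Newick leaf
  name that comes back. Sequences and metadata are never co-transported —
  the ID re-joins them.

The assumption behind both is that external services (alignment, tree
building) preserve sequence identifiers verbatim but nothing else, which
holds for the FASTA/Newick conventions of the common gateways.

## Normalization and naming

Display names like `Gene Product` are normalized to `gene_product`
(lowercase; runs of whitespace/hyphens → one underscore; must then match
`[a-z][a-z0-9_]*`). ARB stores per-entry data under short lowercase keys,
so a single deterministic mapping keeps the database header, the filter's
`WRITE` targets, and relabel lookups consistent. The mapping is
idempotent; names that normalize to something illegal (e.g. a leading
digit) are rejected rather than repaired. Blank lines and `#` comments in
the meta-labels file are ignored so schemas can be annotated.

## Unique IDs

`prefix + base-36 counter`, counter fixed at width 6, total ≤ 8
characters (ARB's `name` key is conventionally short). The counter is
deterministic given `(prefix, start)` — no randomness — so re-running an
extraction reproduces byte-identical artifacts; capacity is 36⁶ ≈ 2.2
billion IDs per prefix. The ID→accession map is kept in a manifest so
metadata can be added to existing entries later.

## Field resolution

`extract_field` is total: it resolves through (1) built-in resolvers for
well-known names (`accession`, `gi`, `version`, `definition`,
`organism`/`species`, `genus`, `phylum`, `product`/`gene_product`,
`gene`, `locus_tag`, `date`, `author`, `journal`), then (2) the source
feature's qualifiers (covering environmental fields such as `ph`,
`salinity`, `temperature` when a submitter recorded them), then (3)
qualifiers pooled over the remaining features (first occurrence in file
order wins), then (4) the empty string. Missing data is an empty cell,
not an error, because realistic schemas include fields most records lack.

Two resolvers are heuristic by default: `genus` is the first whitespace
token of the binomial, and `phylum` is the second entry of the record's
own ORGANISM lineage (lineages conventionally read domain; phylum; ...).
For fungal records whose lineage interposes a kingdom, the positional
default returns `Fungi`; pointing the extractor at an offline NCBI
taxdump directory (`names.dmp`/`nodes.dmp`) replaces both heuristics with
true rank lookups. Values are sanitized (tabs/newlines → single space) at
extraction so the tab-delimited header stays parseable; the sanitization
is lossy by design and applied nowhere else.

## The database dialect

Header: `>` + uid + TAB + value₁ + TAB + ... + valueₙ; sequence on the
following lines, wrapped at 70 columns on write (any wrapping accepted on
read, since the column is unspecified in the wild). Reading is strict
about cell count — a header with the wrong number of cells means the
schema and the database have drifted, exactly the corruption the unique-ID
system exists to prevent, so it fails with the uid and line number rather
than padding. Gap characters `-` and `.` are both accepted (ARB uses
dot-style gaps in places); `-` is what the writer emits. Aligned FASTA
imports (e.g. a curated CDD family) keep their gaps, and headers that
already look like minted IDs are preserved rather than re-minted, so
previously built trees stay linked.

## The import filter and its reference interpreter

`build_import_filter` is a pure function of the schema: one rule per
header column, column 0 → ARB's reserved `name` field (ARB's tree import
matches leaf names against `name`, which is exactly the uid linkage),
column *i* → label *i−1*. The emitted dialect is a conservative subset of
ARB's directives — `AUTODETECT`, `KEYWIDTH`, `BEGIN`, one
`MATCH`/`TABCOLUMN`/`WRITE` block per field, `SEQUENCEAFTER`,
`SEQUENCEEND`, `END` — with a single extraction primitive (`TABCOLUMN n`:
tab-split the header, take zero-based cell *n*) instead of ARB's general
search-replace micro-syntax. That choice isolates the only part whose
semantics cannot be verified without a live ARB: the in-repo interpreter
(`apply_filter`) defines the directive subset's behavior exactly, and the
round-trip property *apply(build(schema), write(db)) == db* is testable
offline. Whether a given ARB release's own importer accepts the file
verbatim must still be validated against a real installation; a bit-exact
SRT backend could be swapped in behind `FieldRule` without changing the
module surface. One `MATCH` block per field (rather than one
mega-expression) keeps renders diffable.

## Tree linkage and relabeling

Leaves may be a strict subset of the database (users prune before tree
building); a leaf absent from the database breaks the linkage guarantee
and raises an error listing every unmatched label. Duplicate leaf labels
are rejected. Relabeling replaces each leaf label with joined metadata
values (pseudo-field `uid` available; `keep_uid` prepends the ID to
restore uniqueness when display values repeat) on a copy of the tree —
topology, branch lengths and internal (support) labels are untouched, and
labels containing Newick-special characters are quoted. The uid-labeled
tree remains the canonical artifact for ARB's tree import; relabeled
trees are for viewers. Newick I/O is dendropy's, with underscores
preserved verbatim on read and spaces quoted (not underscore-substituted)
on write.

## Synthetic fixtures

The generator emulates single-gene GenBank records of the kind the
pipeline targets — bacterial and fungal sugar-transporter genes with
identification, taxonomy, functional, environmental and publication
metadata — emitting flat files through Biopython's GenBank writer so the
layout is canonical. Every planted value is recorded as ground truth,
computed from the planted inputs by the documented rules independently of
the extractor, which makes full value recovery an exact, seedable test.
Deliberately awkward cases are included because each exercises a
documented decision: a product qualifier containing a literal tab
(sanitization), environmental qualifiers on only some records
(missing → empty cell), lineages with trailing periods (lineage
normalization).

What the fixtures do **not** emulate: multi-gene and contig/CON records,
EMBL format, qualifier continuation edge cases beyond what Biopython's
writer produces, GI numbers (modern flat files omit them; the GI resolver
is tested on a hand-written legacy record), and real taxonomic breadth.
Passing tests therefore demonstrate correctness of the pipeline's
contracts on well-formed single-gene records, not robustness to every
flat file in GenBank.

Randomized databases for round-trip corpora draw metadata from a
printable alphabet with spaces and punctuation (~10% empty cells) and
random nucleotide sequences of 20–120 residues, optionally gapped;
random trees are built by iteratively joining random pairs with branch
lengths uniform on (0.01, 0.5). Test and acceptance corpora use 200
databases of 1–12 fields × 1–500 records — large enough to hit the
empty-cell, gap and quoting paths many times while keeping the full suite
in seconds.

## The cost estimator

`estimate_pairwise_alignments(n, t_per_pair)` returns the exact integer
`n(n−1)/2` and the implied wall time. At the motivating corpus size
(n = 10 752, 0.019 s/pair) that is 57 797 376 pairs ≈ 12.7 days — the
arithmetic that justifies outsourcing. The per-pair time is a measured
input, not a model; nothing here accounts for progressive-alignment
overhead beyond the pairwise stage.

## Numerical and degenerate-input choices

Everything is seeded; no generator reads the clock or the network.
Branch lengths are carried as dendropy parses them and printed without
reformatting beyond float round-trip. Empty metadata cells render as
empty tab-delimited cells and import as empty strings. A database must
contain ≥ 1 record, a tree ≥ 2 leaves; single-record databases are
exercised by the corpora (they are valid databases, just unlinkable to a
tree). CLI exit codes: 0 success, 2 validation error, 3 I/O error.

## Known limitations

* No network fetching (NCBI/PFAM/CDD), no job submission to gateways, no
  ARB process control — the user performs those steps, as intended.
* ARB byte-compatibility of the emitted `.ift` is defined by this
  package's reference interpreter, not certified against an ARB release.
* Rank resolution without a taxdump is positional and can mislabel
  non-bacterial lineages (documented above).
* One tree per Newick file; Nexus is out of scope.
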