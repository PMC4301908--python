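# arbkit

Middleware between a local [ARB](http://www.arb-home.de/) installation and
cloud phylogenetics services.

Molecular ecologists routinely assemble corpora of thousands of sequences
with rich, heterogeneous metadata (taxonomy, environmental measurements,
functional annotation, publication details), then need alignments and
phylogenies that are far too expensive to compute locally: an
all-against-all progressive alignment needs **n(n−1)/2** pairwise
alignments, so a ~10k-sequence family already implies tens of millions of
them. Web gateways (e.g. Cipres/XSEDE running MAFFT or RAxML) solve the
compute problem but offer none of ARB's interactive curation, tree
exploration or probe design. `arbkit` closes the gap:

1. **Meta-labels schema** — a user-authored text file lists the metadata
   field names; it becomes the single schema for every downstream artifact.
2. **Extraction** — GenBank flat files are parsed, the requested fields
   resolved (identification, taxonomy, functional, environmental,
   publication), and every entry is minted a short, stable **unique ID**
   (≤ 8 characters: prefix + fixed-width base-36 counter).
3. **Custom database** — a FASTA dialect whose header is a TAB-delimited
   row: unique ID first, then one cell per meta-label, in schema order.
4. **Import filter** — the matching ARB `.ift` import filter is generated
   automatically from the schema alone, so ARB can ingest the custom
   database with the unique ID stored in its reserved `name` key.
5. **Outsourcing** — a bare-ID FASTA (headers carry only the unique ID) is
   exported for external alignment/tree building.
6. **Linkage** — the Newick tree that comes back has unique IDs as leaf
   names; `arbkit` verifies that every leaf resolves to exactly one
   database record and can relabel leaves with any metadata fields (e.g.
   the gene product) without touching topology or branch lengths.

The unique ID is the load-bearing idea: it survives the round trip through
external services unmodified and is the join key that re-attaches the
returned alignment/tree to the local metadata.

## Worked example

Generate a self-contained synthetic demo (meta-labels file, GenBank
records, and the expected downstream artifacts), then run the pipeline:

```sh
arbkit make-fixtures --out-dir demo --n-records 8 --seed 42
arbkit extract --meta-labels demo/meta_labels.txt \
               --genbank demo/records.gb --out-dir run
# -> "8 records -> run/database.fasta"
arbkit build-filter --meta-labels demo/meta_labels.txt --out run/custom_import_filter.ift
arbkit export --meta-labels demo/meta_labels.txt \
              --database run/database.fasta --out run/sequences.fasta
```

`run/database.fasta` starts like this — header = unique ID, accession,
species, gene product, pH (empty here: the record carried no pH), year:

```
>sq000001	SD000001	Aspergillus niger	sugar transporter		2004
TAAACCACTCTGACTGGCCGAATAGGGATATAGGCAACGACATGTGCGGCGACCCTTGCGACAGTGACGC
TTTCGCCGTTGC
```

`run/sequences.fasta` is the same sequence under a bare `>sq000001`
header — that file is what you submit to an external alignment/tree
service. When the tree comes back (the demo ships one as `demo/tree.nwk`),
check and relabel it:

```sh
arbkit check-tree --meta-labels demo/meta_labels.txt \
                  --database run/database.fasta --tree demo/tree.nwk
# -> "n_leaves=8 n_matched=8"
arbkit relabel --meta-labels demo/meta_labels.txt \
               --database run/database.fasta --tree demo/tree.nwk \
               --fields gene_product --out run/relabeled.nwk
```

`run/relabeled.nwk` shows products instead of IDs on the leaves (quoted
where needed), with the topology untouched. Finally, the cost arithmetic
that motivates outsourcing in the first place:

```sh
arbkit estimate -n 10752 --t-per-pair 0.019
# n_pairs=57797376
# total_seconds=1098150.1
# total_days=12.71
```

i.e. a 10,752-sequence family at 0.019 s per pairwise alignment would
keep a desktop busy for nearly two weeks — versus minutes on a gateway.

The same operations are available as library functions
(`arbkit.parse_meta_labels`, `build_records`, `write_database`,
`build_import_filter`, `apply_filter`, `link_tree`, `relabel_leaves`, ...);
the CLI is a thin wrapper.

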