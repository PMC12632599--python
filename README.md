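# seqcol

Content-derived identifiers, retrieval/comparison API, and compatibility
analytics for collections of named sequences (reference genomes,
transcriptomes, or any FASTA).

A sequence collection is represented as collated arrays of sequence
`names`, `lengths`, and `sequences` (per-sequence content digests). Each
attribute is canonicalized with the RFC 8785 JSON Canonicalization Scheme
and digested with truncated SHA-512 (`sha512t24u`: first 24 bytes,
base64url, no padding); digesting the map of *inherent* attribute digests
yields the collection's top-level identifier. Identical inputs produce
identical identifiers on any system, with no naming authority involved.

Beyond exact identity, the comparison layer quantifies compatibility:
shared/unique elements per attribute, element order, Jaccard similarity
and overlap proportions (OPA/OPB), and an inferred set relationship
(identical / subset / partial overlap / disjoint) — enough to recognize
order-relaxed identity, renamed-but-identical sequences, shared
coordinate systems, and subset relationships such as "no-alt" variants
or assembly patch chains.

## CLI

```sh
# top-level digest of a FASTA (plain or .gz); levels 0/1/2
seqcol digest genome.fa
seqcol digest genome.fa --level 2 --no-seq-prefix

# compare two collections (FASTA or level-2 JSON)
seqcol compare a.fa b.fa --scores --interpret

# generate a synthetic fixture universe with planted ground truth
seqcol fixtures --seed 1 --out fixtures/

# batch census over a manifest (TSV: label, provider, genome_class, path)
seqcol analyze --manifest fixtures/manifest.tsv --out analysis/

# serve the retrieval/comparison API (stdlib HTTP, optional SQLite store)
seqcol serve --port 8100 --db store.db --load fixtures/manifest.tsv
```

Server endpoints: `/service-info`, `/collection/{digest}?level=0|1|2`,
`/comparison/{a}/{b}`, `POST /comparison/{a}` (ad-hoc level-2 body),
`/list/collections?page&page_size&{attr}={digest}`, and
`/attribute/collection/{attr}/{digest}`. Attribute values are stored
once, keyed by attribute digest, so collections sharing e.g. a
coordinate system share storage.

Manifests for real references follow the same four-column layout, e.g.

```
label            provider  genome_class  path
hg38-primary     ucsc      hg38          genomes/hg38.primary.fa.gz
GRCh38-p14       ncbi      hg38          genomes/GCA_000001405.29.fa.gz
```

## Notes on digests

- Residues are uppercased before digesting: soft-masked and unmasked
  copies of a genome share all digests; hard-masking (N substitution)
  changes sequence digests but not lengths.
- Sequence identifiers carry the `SQ.` prefix by default; disabling it
  (`--no-seq-prefix`) changes every collection digest.
- Sequence names are the first whitespace-delimited header token by
  default (`--name-policy full-header` to override).
- `sorted_name_length_pairs` identifies a coordinate system irrespective
  of sequence order and content; it and the other computed attributes
  (`name_length_pairs`, `sorted_sequences`) are non-inherent: served and
  filterable, but excluded from the top-level digest.

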