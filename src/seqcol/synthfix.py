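"""Deterministic synthetic-genome fixtures with planted ground truth.

Emulates the kinds of variation real reference providers introduce —
renamed sequences, reordered sequences, subsets ("no-alt" and patch
chains), soft/hard masking, point mutations, decoy additions, and exact
duplicates under different labels — and records, for every planted
relation, the expected comparison outcome.

Ground-truth relations are computed set-wise from the raw residue
content at build time (plain Python set operations on names, lengths,
uppercased sequences, and (name, length) pairs), independently of the
digest and comparison machinery they are later checked against.

Everything is reproducible from the seed: the PRNG is the stdlib
Mersenne Twister (``random.Random``), whose algorithm is fixed across
platforms and Python versions.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from .fasta import FastaEntry, digest_fasta_entries, parse_fasta

__all__ = [
    "FixtureUniverse",
    "generate_genome",
    "derive_variant",
    "build_test_universe",
]

_WRAP = 60
_STYLES = {
    "ucsc": lambda i, old: f"chr{i + 1}",
    "ensembl": lambda i, old: str(i + 1),
    "accession": lambda i, old: f"CM{i + 1:06d}.1",
}


def _entries(fasta: str) -> list[FastaEntry]:
    return list(parse_fasta(io.StringIO(fasta)))


def _emit(entries: Iterable[FastaEntry]) -> str:
    chunks = []
    for e in entries:
        chunks.append(f">{e.header}\n")
        for i in range(0, len(e.residues), _WRAP):
            chunks.append(e.residues[i : i + _WRAP] + "\n")
    return "".join(chunks)


def _random_residues(rng: random.Random, length: int, alphabet: str, n_fraction: float) -> str:
    bases = rng.choices(alphabet, k=length)
    if n_fraction > 0:
        for i in range(length):
            if rng.random() < n_fraction:
                bases[i] = "N"
    return "".join(bases)


def generate_genome(
    n_seqs: int,
    length_range: tuple[int, int],
    alphabet: str = "ACGT",
    seed: int = 0,
    name_prefix: str = "chr",
    n_fraction: float = 0.01,
) -> str:
    """Random FASTA with records ``{prefix}1..{prefix}N``; deterministic in seed."""
    lo, hi = length_range
    if n_seqs < 1 or lo < 1 or hi < lo:
        raise ValueError(f"invalid genome parameters: n_seqs={n_seqs}, range={length_range}")
    rng = random.Random(seed)
    entries = []
    for i in range(n_seqs):
        length = rng.randint(lo, hi)
        entries.append(
            FastaEntry(
                header=f"{name_prefix}{i + 1}",
                name=f"{name_prefix}{i + 1}",
                residues=_random_residues(rng, length, alphabet, n_fraction),
            )
        )
    return _emit(entries)


def derive_variant(base: str, op: str, **params: Any) -> tuple[str, dict[str, Any]]:
    """Apply one controlled variation to FASTA content.

    ``op`` is one of ``rename``, ``reorder``, ``subset``, ``soft_mask``,
    ``hard_mask``, ``point_mutate``, ``append_decoys``. Returns the
    variant FASTA plus a truth record stating what changed and the
    expected per-attribute comparison outcome versus the base.
    """
    entries = _entries(base)
    truth: dict[str, Any] = {"op": op, **{k: v for k, v in params.items()}}

    if op == "rename":
        style = params["style"]
        if style not in _STYLES:
            raise ValueError(f"unknown rename style: {style!r}")
        renamer = _STYLES[style]
        out = [
            FastaEntry(header=renamer(i, e.name), name=renamer(i, e.name), residues=e.residues)
            for i, e in enumerate(entries)
        ]
        truth["expects"] = {"sequences": "identical", "lengths": "identical", "names": "changed"}
        return _emit(out), truth

    if op == "reorder":
        rng = random.Random(params["seed"])
        if len(entries) < 2:
            raise ValueError("cannot reorder a single-record collection")
        perm = list(range(len(entries)))
        while perm == list(range(len(entries))):
            rng.shuffle(perm)
        truth["permutation"] = perm
        truth["expects"] = {"all-attributes": "identical-as-sets", "order": "changed"}
        return _emit([entries[i] for i in perm]), truth

    if op == "subset":
        kept = sorted(params["kept_indices"])
        if not kept:
            raise ValueError("subset of zero indices")
        if kept[-1] >= len(entries) or kept[0] < 0:
            raise ValueError("kept index out of range")
        truth["kept_indices"] = kept
        truth["expects"] = {"all-attributes": "a-subset-of-b" if len(kept) < len(entries) else "identical"}
        return _emit([entries[i] for i in kept]), truth

    if op in ("soft_mask", "hard_mask"):
        fraction = params["fraction"]
        rng = random.Random(params["seed"])
        out = []
        for e in entries:
            chars = list(e.residues)
            candidates = [i for i, c in enumerate(chars) if c.upper() != "N"]
            k = max(1, int(len(candidates) * fraction)) if candidates else 0
            for i in rng.sample(candidates, k):
                chars[i] = chars[i].lower() if op == "soft_mask" else "N"
            out.append(FastaEntry(header=e.header, name=e.name, residues="".join(chars)))
        truth["expects"] = (
            {"level0": "identical"}
            if op == "soft_mask"
            else {"sequences": "changed", "lengths": "identical", "names": "identical"}
        )
        return _emit(out), truth

    if op == "point_mutate":
        k = params["k"]
        rng = random.Random(params["seed"])
        idx = params.get("record_index", rng.randrange(len(entries)))
        target = entries[idx]
        if k > len(target.residues):
            raise ValueError(f"k={k} exceeds residue count of {target.name!r}")
        chars = list(target.residues)
        positions = rng.sample(range(len(chars)), k)
        for pos in positions:
            current = chars[pos].upper()
            chars[pos] = rng.choice([b for b in "ACGT" if b != current])
        out = list(entries)
        out[idx] = FastaEntry(header=target.header, name=target.name, residues="".join(chars))
        truth.update(record=target.name, record_index=idx, positions=sorted(positions))
        truth["expects"] = {"changed_sequence_digests": 1, "lengths": "identical"}
        return _emit(out), truth

    if op == "append_decoys":
        m = params["m"]
        rng = random.Random(params["seed"] ^ 0x5EC0C01)  # disjoint seed stream
        length_range = params.get("length_range", (1000, 1200))
        existing = {e.residues.upper() for e in entries}
        decoys = []
        for i in range(m):
            residues = _random_residues(rng, rng.randint(*length_range), "ACGT", 0.0)
            assert residues.upper() not in existing, "decoy collided with a base sequence"
            name = f"decoy{i + 1}"
            decoys.append(FastaEntry(header=name, name=name, residues=residues))
        truth["decoy_names"] = [d.name for d in decoys]
        truth["expects"] = {"all-attributes": "b-superset-of-a"}
        return _emit(entries + decoys), truth

    raise ValueError(f"unknown variant op: {op!r}")


# --- set-wise ground-truth relations (independent of the digest pipeline) ---


def _attribute_sets(fasta: str) -> dict[str, set]:
    entries = _entries(fasta)
    return {
        "names": {e.name for e in entries},
        "lengths": {len(e.residues) for e in entries},
        "sequences": {e.residues.upper() for e in entries},
        "name_length_pairs": {(e.name, len(e.residues)) for e in entries},
    }


def _set_relation(sa: set, sb: set) -> str:
    if sa == sb:
        return "identical-as-sets"
    if sa < sb:
        return "a-subset-of-b"
    if sb < sa:
        return "b-subset-of-a"
    if not sa & sb:
        return "disjoint"
    return "partial-overlap"


@dataclass
class FixtureUniverse:
    """A labelled set of FASTA collections plus machine-readable ground truth."""

    seed: int
    collections: dict[str, str]
    providers: dict[str, str]
    classes: dict[str, str]
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.collections)

    def write(self, outdir: str | Path) -> Path:
        """Write FASTA files, manifest.tsv and truth.json; return manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = ["label\tprovider\tgenome_class\tpath"]
        for label, fasta in self.collections.items():
            path = outdir / f"{label}.fa"
            path.write_text(fasta)
            rows.append(
                f"{label}\t{self.providers[label]}\t{self.classes[label]}\t{path.name}"
            )
        manifest = outdir / "manifest.tsv"
        manifest.write_text("\n".join(rows) + "\n")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")
        return manifest


def build_test_universe(seed: int = 0) -> FixtureUniverse:
    """Thirteen collections covering every planted relation class.

    Two base genomes (disjoint in names, lengths and content) plus
    derivatives: a byte-level rewrap duplicate, a soft-mask digest
    duplicate, a hard mask, a rename, a reorder, a strict subset chain of
    length three (patch emulation), a 2-point mutation, a decoy-augmented
    copy, and a duplicated + renamed second genome.
    """
    genome_a = generate_genome(6, (300, 600), seed=seed, name_prefix="chr")
    genome_b = generate_genome(4, (700, 900), seed=seed + 1, name_prefix="scaffold")

    collections: dict[str, str] = {}
    providers: dict[str, str] = {}
    classes: dict[str, str] = {}
    ops: dict[str, dict[str, Any]] = {}

    def add(label: str, fasta: str, provider: str, genome_class: str, truth: dict | None = None) -> None:
        collections[label] = fasta
        providers[label] = provider
        classes[label] = genome_class
        if truth is not None:
            ops[label] = truth

    add("A-ncbi", genome_a, "ncbi", "gA")
    # identical content, different line wrapping -> exact duplicate by digest
    entries_a = _entries(genome_a)
    add("A-broad", "".join(f">{e.header}\n{e.residues}\n" for e in entries_a), "broad", "gA")

    fasta, t = derive_variant(genome_a, "soft_mask", fraction=0.3, seed=seed + 10)
    add("A-ucsc-softmask", fasta, "ucsc", "gA", t)
    fasta, t = derive_variant(genome_a, "hard_mask", fraction=0.3, seed=seed + 11)
    add("A-ucsc-hardmask", fasta, "ucsc", "gA", t)
    fasta, t = derive_variant(genome_a, "rename", style="ensembl")
    add("A-ensembl-renamed", fasta, "ensembl", "gA", t)
    fasta, t = derive_variant(genome_a, "reorder", seed=seed + 12)
    add("A-gencode-reordered", fasta, "gencode", "gA", t)
    fasta, t = derive_variant(genome_a, "subset", kept_indices=[0, 1, 2, 3])
    add("A-noalt", fasta, "ncbi", "gA", t)
    fasta, t = derive_variant(collections["A-noalt"], "subset", kept_indices=[0, 1, 2])
    add("A-noalt-min", fasta, "ncbi", "gA", t)
    fasta, t = derive_variant(genome_a, "point_mutate", k=2, seed=seed + 13)
    add("A-ena-mut", fasta, "ena", "gA", t)
    fasta, t = derive_variant(genome_a, "append_decoys", m=3, seed=seed + 14)
    add("A-ncbi-decoy", fasta, "ncbi", "gA", t)

    add("B-ncbi", genome_b, "ncbi", "gB")
    fasta, t = derive_variant(genome_b, "rename", style="accession")
    add("B-ena-renamed", fasta, "ena", "gB", t)
    add("B-igenomes", genome_b, "igenomes", "gB")

    labels = list(collections)

    # duplicate groups by ordered (name, uppercased residues) content
    content_key = {
        lbl: tuple((e.name, e.residues.upper()) for e in _entries(fa))
        for lbl, fa in collections.items()
    }
    groups: dict[tuple, list[str]] = {}
    for lbl, key in content_key.items():
        groups.setdefault(key, []).append(lbl)
    duplicate_groups = sorted(sorted(g) for g in groups.values() if len(g) > 1)
    n_total = len(labels)
    n_distinct = len(groups)

    attr_sets = {lbl: _attribute_sets(fa) for lbl, fa in collections.items()}
    expected_relations: dict[str, dict[str, str]] = {}
    for attr in ("names", "lengths", "sequences", "name_length_pairs"):
        table: dict[str, str] = {}
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                table[f"{la}|{lb}"] = _set_relation(
                    attr_sets[la][attr], attr_sets[lb][attr]
                )
        expected_relations[attr] = table

    truth = {
        "seed": seed,
        "labels": labels,
        "providers": providers,
        "classes": classes,
        "variant_ops": ops,
        "duplicate_groups": duplicate_groups,
        "n_total": n_total,
        "n_distinct": n_distinct,
        "duplicate_fraction": (n_total - n_distinct) / n_total,
        "duplicate_member_fraction": sum(len(g) for g in duplicate_groups) / n_total,
        "rename_pairs": [["A-ncbi", "A-ensembl-renamed"], ["B-ncbi", "B-ena-renamed"]],
        "reorder_pairs": [["A-ncbi", "A-gencode-reordered"]],
        "subset_pairs": [
            {"sub": "A-noalt", "sup": "A-ncbi", "kept_indices": [0, 1, 2, 3]},
            {"sub": "A-noalt-min", "sup": "A-noalt", "kept_indices": [0, 1, 2]},
            {"sub": "A-noalt-min", "sup": "A-ncbi", "kept_indices": [0, 1, 2]},
            {"sub": "A-ncbi", "sup": "A-ncbi-decoy", "kept_indices": [0, 1, 2, 3, 4, 5]},
        ],
        "mask_pairs": [
            {"base": "A-ncbi", "variant": "A-ucsc-softmask", "kind": "soft"},
            {"base": "A-ncbi", "variant": "A-ucsc-hardmask", "kind": "hard"},
        ],
        "mutation_pairs": [
            {"base": "A-ncbi", "variant": "A-ena-mut", "k": 2, **{
                k: v for k, v in ops["A-ena-mut"].items() if k in ("record", "record_index")
            }}
        ],
        "decoy_pairs": [
            {"base": "A-ncbi", "variant": "A-ncbi-decoy", "m": 3,
             "decoy_names": ops["A-ncbi-decoy"]["decoy_names"]}
        ],
        "expected_relations": expected_relations,
        # declared digests for the ingest round-trip check
        "level0": {
            lbl: digest_fasta_entries(_entries(fa)).level0
            for lbl, fa in collections.items()
        },
    }
    return FixtureUniverse(
        seed=seed,
        collections=collections,
        providers=providers,
        classes=classes,
        truth=truth,
    )
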