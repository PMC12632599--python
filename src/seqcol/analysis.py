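"""Batch compatibility analytics over a manifest of collections.

Reproduces the reference-genome census operations at any scale: pairwise
Jaccard/overlap matrices per attribute, duplicate and identical-attribute
grouping, strict-subset detection, sequence-presence matrices per genome
class, provider-level summaries, and ranked one-vs-many comparison.

All outputs are deterministic: matrices are reproducible bit-for-bit
across runs, and tabular exports use sorted, documented column order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import SimilarityScores, RelationshipVerdict, _as_key, classify_relationship
from .fasta import digest_fasta, digest_fasta_entries, parse_fasta
from .model import DigestedSeqcol, SeqcolSchema

__all__ = [
    "ManifestEntry",
    "CollectionManifest",
    "PairwiseMatrix",
    "DuplicateCensus",
    "PresenceMatrix",
    "DensityHistogram",
    "DEFAULT_ATTRIBUTES",
    "pairwise_matrices",
    "find_duplicates",
    "find_identical_attribute_sets",
    "find_subsets",
    "sequence_presence",
    "provider_summary",
    "compare_one_vs_many",
    "density_summary",
    "write_analysis",
]

#: The four attributes compared throughout the batch analyses.
DEFAULT_ATTRIBUTES = ("names", "lengths", "sequences", "name_length_pairs")


@dataclass
class ManifestEntry:
    label: str
    provider: str = ""
    genome_class: str = ""
    path: str | None = None
    collection: DigestedSeqcol | None = None

    def resolve(self, schema: SeqcolSchema | None = None) -> DigestedSeqcol:
        if self.collection is None:
            if self.path is None:
                raise ValueError(f"manifest entry {self.label!r} has neither path nor collection")
            try:
                self.collection = digest_fasta(self.path, schema=schema)
            except OSError as exc:
                raise ValueError(f"cannot resolve manifest entry {self.label!r}: {exc}") from exc
        return self.collection


@dataclass
class CollectionManifest:
    """Labelled collections with provider and genome-class annotations."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate manifest labels: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def resolve(self, schema: SeqcolSchema | None = None) -> dict[str, DigestedSeqcol]:
        return {e.label: e.resolve(schema) for e in self.entries}

    @classmethod
    def read(cls, path: str | Path) -> "CollectionManifest":
        """Read a TSV/CSV manifest with columns label, provider, genome_class, path."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
        missing = {"label", "path"} - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            p = Path(row.path)
            if not p.is_absolute():
                p = path.parent / p
            entries.append(
                ManifestEntry(
                    label=row.label,
                    provider=getattr(row, "provider", ""),
                    genome_class=getattr(row, "genome_class", ""),
                    path=str(p),
                )
            )
        return cls(entries)

    @classmethod
    def from_universe(cls, universe, schema: SeqcolSchema | None = None) -> "CollectionManifest":
        """Build an in-memory manifest from a synthetic fixture universe."""
        entries = []
        for label, fasta in universe.collections.items():
            digested = digest_fasta_entries(parse_fasta(io.StringIO(fasta)), schema=schema)
            entries.append(
                ManifestEntry(
                    label=label,
                    provider=universe.providers[label],
                    genome_class=universe.classes[label],
                    collection=digested,
                )
            )
        return cls(entries)


def _element_sets(
    collections: Mapping[str, DigestedSeqcol], attribute: str
) -> dict[str, frozenset[Hashable]]:
    out = {}
    for label, coll in collections.items():
        values = coll.level2.get(attribute, [])
        out[label] = frozenset(_as_key(v) for v in values)
    return out


def _scores_from_sets(sa: frozenset, sb: frozenset) -> SimilarityScores:
    inter = len(sa & sb)
    union = len(sa | sb)
    return SimilarityScores(
        jaccard=Fraction(inter, union) if union else None,
        opa=Fraction(inter, len(sa)) if sa else None,
        opb=Fraction(inter, len(sb)) if sb else None,
    )


@dataclass
class PairwiseMatrix:
    """Square score matrices over all unordered label pairs for one attribute."""

    attribute: str
    labels: list[str]
    jaccard: np.ndarray
    opa: np.ndarray
    opb: np.ndarray
    n_pairs: int

    def to_frame(self, which: str = "jaccard") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.labels, columns=self.labels)

    def long_form(self) -> pd.DataFrame:
        """Tidy rows (attribute, label_a, label_b, jaccard, opa, opb) over unordered pairs."""
        rows = []
        for i, la in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                rows.append(
                    {
                        "attribute": self.attribute,
                        "label_a": la,
                        "label_b": self.labels[j],
                        "jaccard": self.jaccard[i, j],
                        "opa": self.opa[i, j],
                        "opb": self.opb[i, j],
                    }
                )
        return pd.DataFrame(rows)


def pairwise_matrices(
    manifest: CollectionManifest,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
    use_short_circuit: bool = True,
) -> list[PairwiseMatrix]:
    """Score every unordered pair of manifest collections per attribute.

    With ``use_short_circuit`` enabled, equal level-1 digests imply all
    scores are 1 without element comparison; results are identical either
    way. Undefined cells (an empty side) are NaN.
    """
    collections = manifest.resolve()
    labels = manifest.labels
    n = len(labels)
    out = []
    for attribute in attributes:
        sets = _element_sets(collections, attribute)
        jac = np.full((n, n), np.nan)
        opa = np.full((n, n), np.nan)
        opb = np.full((n, n), np.nan)
        n_pairs = 0
        for i, la in enumerate(labels):
            if sets[la]:
                jac[i, i] = opa[i, i] = opb[i, i] = 1.0
            for j in range(i + 1, n):
                lb = labels[j]
                n_pairs += 1
                if use_short_circuit and collections[la].level1.get(
                    attribute
                ) == collections[lb].level1.get(attribute) and attribute in collections[la].level1:
                    s = SimilarityScores(Fraction(1), Fraction(1), Fraction(1))
                else:
                    s = _scores_from_sets(sets[la], sets[lb])
                jac[i, j] = jac[j, i] = np.nan if s.jaccard is None else float(s.jaccard)
                opa[i, j] = opb[j, i] = np.nan if s.opa is None else float(s.opa)
                opb[i, j] = opa[j, i] = np.nan if s.opb is None else float(s.opb)
        out.append(
            PairwiseMatrix(
                attribute=attribute, labels=labels, jaccard=jac, opa=opa, opb=opb, n_pairs=n_pairs
            )
        )
    return out


@dataclass
class DuplicateCensus:
    groups: list[list[str]]
    n_total: int
    n_distinct: int

    @property
    def duplicate_fraction(self) -> Fraction:
        """(n_total - n_distinct) / n_total — zero when all digests differ."""
        if self.n_total == 0:
            return Fraction(0)
        return Fraction(self.n_total - self.n_distinct, self.n_total)

    @property
    def member_fraction(self) -> Fraction:
        """Alternative census: members of any duplicate group / n_total."""
        if self.n_total == 0:
            return Fraction(0)
        return Fraction(sum(len(g) for g in self.groups), self.n_total)


def _group_by(manifest: CollectionManifest, key) -> DuplicateCensus:
    collections = manifest.resolve()
    groups: dict[str, list[str]] = {}
    for label in manifest.labels:
        groups.setdefault(key(collections[label]), []).append(label)
    return DuplicateCensus(
        groups=sorted(sorted(g) for g in groups.values() if len(g) > 1),
        n_total=len(manifest),
        n_distinct=len(groups),
    )


def find_duplicates(manifest: CollectionManifest) -> DuplicateCensus:
    """Group labels sharing a top-level digest; fraction per the stated formula."""
    return _group_by(manifest, lambda c: c.level0)


def find_identical_attribute_sets(
    manifest: CollectionManifest, attribute: str
) -> DuplicateCensus:
    """As :func:`find_duplicates`, but keyed on one attribute's level-1 digest."""
    return _group_by(manifest, lambda c: c.level1.get(attribute, ""))


def find_subsets(
    manifest: CollectionManifest, attribute: str
) -> list[tuple[str, str]]:
    """Ordered pairs (A, B) where A's unique elements are a strict subset of B's."""
    collections = manifest.resolve()
    sets = _element_sets(collections, attribute)
    labels = manifest.labels
    return [
        (la, lb)
        for la in labels
        for lb in labels
        if la != lb and sets[la] < sets[lb]
    ]


@dataclass
class PresenceMatrix:
    genome_class: str
    matrix: pd.DataFrame  # rows: sequence identifiers; cols: labels; bool cells

    @property
    def row_frequency(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def n_sequences(self) -> int:
        return len(self.matrix)


def sequence_presence(
    manifest: CollectionManifest, genome_class: str
) -> PresenceMatrix:
    """Which sequences appear in which collections of one genome class."""
    entries = [e for e in manifest.entries if e.genome_class == genome_class]
    if not entries:
        raise ValueError(f"unknown genome class: {genome_class!r}")
    collections = {e.label: e.resolve() for e in entries}
    seq_sets = {l: set(c.level2.get("sequences", [])) for l, c in collections.items()}
    rows = sorted(set().union(*seq_sets.values()))
    labels = [e.label for e in entries]
    data = {l: [s in seq_sets[l] for s in rows] for l in labels}
    return PresenceMatrix(
        genome_class=genome_class,
        matrix=pd.DataFrame(data, index=rows, columns=labels, dtype=bool),
    )


def provider_summary(
    matrices: Iterable[PairwiseMatrix],
    manifest: CollectionManifest,
    within_only: bool = False,
) -> pd.DataFrame:
    """Per-provider mean Jaccard and median pairwise difference per attribute.

    A pair counts toward a provider when either member belongs to it (or
    both, with ``within_only``); undefined cells are excluded. Columns:
    provider, attribute, mean_jaccard, median_difference, n_pairs.
    """
    provider_of = {e.label: e.provider for e in manifest.entries}
    providers = sorted(set(provider_of.values()))
    rows = []
    for m in matrices:
        idx = {l: i for i, l in enumerate(m.labels)}
        for provider in providers:
            vals = []
            for i, la in enumerate(m.labels):
                for j in range(i + 1, len(m.labels)):
                    lb = m.labels[j]
                    in_a = provider_of[la] == provider
                    in_b = provider_of[lb] == provider
                    hit = (in_a and in_b) if within_only else (in_a or in_b)
                    if hit and not np.isnan(m.jaccard[i, j]):
                        vals.append(m.jaccard[i, j])
            rows.append(
                {
                    "provider": provider,
                    "attribute": m.attribute,
                    "mean_jaccard": float(np.mean(vals)) if vals else np.nan,
                    "median_difference": float(np.median([1 - v for v in vals])) if vals else np.nan,
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["provider", "attribute", "mean_jaccard", "median_difference", "n_pairs"])


@dataclass
class OneVsManyResult:
    label: str
    scores: dict[str, SimilarityScores]
    verdicts: dict[str, RelationshipVerdict | None]

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "scores": {a: s.to_dict() for a, s in self.scores.items()},
            "verdicts": {
                a: (v.relation if v else None) for a, v in self.verdicts.items()
            },
        }


def compare_one_vs_many(
    query: DigestedSeqcol,
    manifest: CollectionManifest,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
) -> list[OneVsManyResult]:
    """Score a query against every manifest entry; ranked best-first.

    Ranking: sequences Jaccard descending, then name_length_pairs
    Jaccard, then label. The query is always "A" in the scores.
    """
    collections = manifest.resolve()
    q_sets = {a: frozenset(_as_key(v) for v in query.level2.get(a, [])) for a in attributes}
    results = []
    for label in manifest.labels:
        scores: dict[str, SimilarityScores] = {}
        verdicts: dict[str, RelationshipVerdict | None] = {}
        for a in attributes:
            sb = frozenset(_as_key(v) for v in collections[label].level2.get(a, []))
            s = _scores_from_sets(q_sets[a], sb)
            scores[a] = s
            verdicts[a] = (
                classify_relationship(s, attribute=a)
                if s.jaccard is not None and s.opa is not None and s.opb is not None
                else None
            )
        results.append(OneVsManyResult(label=label, scores=scores, verdicts=verdicts))

    def sort_key(r: OneVsManyResult):
        sj = r.scores.get("sequences", SimilarityScores(None, None, None)).jaccard
        nj = r.scores.get("name_length_pairs", SimilarityScores(None, None, None)).jaccard
        return (
            -(sj if sj is not None else Fraction(-1)),
            -(nj if nj is not None else Fraction(-1)),
            r.label,
        )

    return sorted(results, key=sort_key)


@dataclass
class DensityHistogram:
    attribute: str
    counts: list[int]
    edges: list[float]

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def density_summary(matrix: PairwiseMatrix, n_bins: int = 20) -> DensityHistogram:
    """Histogram of off-diagonal upper-triangle scores over fixed [0, 1] bins."""
    n = len(matrix.labels)
    vals = [
        matrix.jaccard[i, j]
        for i in range(n)
        for j in range(i + 1, n)
        if not np.isnan(matrix.jaccard[i, j])
    ]
    counts, edges = np.histogram(vals, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return DensityHistogram(
        attribute=matrix.attribute,
        counts=[int(c) for c in counts],
        edges=[float(e) for e in edges],
    )


def write_analysis(
    manifest: CollectionManifest,
    outdir: str | Path,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
) -> dict[str, Any]:
    """Run the full census and write deterministic CSV/TSV outputs.

    Returns a summary dict (also written as summary.json by the CLI).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices = pairwise_matrices(manifest, attributes)
    long_frames = []
    for m in matrices:
        m.to_frame("jaccard").to_csv(outdir / f"pairwise_jaccard_{m.attribute}.csv")
        m.to_frame("opa").to_csv(outdir / f"pairwise_opa_{m.attribute}.csv")
        long_frames.append(m.long_form())
        hist = density_summary(m)
        pd.DataFrame(
            {"bin_left": hist.edges[:-1], "bin_right": hist.edges[1:], "count": hist.counts}
        ).to_csv(outdir / f"density_{m.attribute}.csv", index=False)
    pd.concat(long_frames, ignore_index=True).to_csv(
        outdir / "pairwise_long.tsv", sep="\t", index=False
    )

    dup = find_duplicates(manifest)
    pd.DataFrame(
        [{"group": i, "label": l} for i, g in enumerate(dup.groups) for l in sorted(g)]
    ).to_csv(outdir / "duplicates.csv", index=False)

    subset_rows = []
    identical_counts = {}
    for a in attributes:
        for la, lb in find_subsets(manifest, a):
            subset_rows.append({"attribute": a, "subset": la, "superset": lb})
        identical_counts[a] = sum(
            len(g) for g in find_identical_attribute_sets(manifest, a).groups
        )
    pd.DataFrame(subset_rows, columns=["attribute", "subset", "superset"]).to_csv(
        outdir / "subsets.csv", index=False
    )

    provider_summary(matrices, manifest).to_csv(outdir / "provider_summary.csv", index=False)

    presence_counts = {}
    for genome_class in sorted({e.genome_class for e in manifest.entries if e.genome_class}):
        pm = sequence_presence(manifest, genome_class)
        frame = pm.matrix.astype(int)
        frame.insert(0, "frequency", pm.row_frequency)
        frame.to_csv(outdir / f"presence_{genome_class}.csv")
        presence_counts[genome_class] = pm.n_sequences

    return {
        "n_collections": len(manifest),
        "n_pairs": matrices[0].n_pairs if matrices else 0,
        "duplicate_fraction": float(dup.duplicate_fraction),
        "duplicate_groups": dup.groups,
        "identical_attribute_members": identical_counts,
        "n_subset_pairs": len(subset_rows),
        "presence_sequence_counts": presence_counts,
    }
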