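"""Sequence-collection data model and the five-step encoding algorithm.

A sequence collection is represented as *collated* arrays — parallel
arrays sharing one index, where element ``i`` of each array describes the
same sequence. The default schema carries three required, inherent
attributes (``names``, ``lengths``, ``sequences``) plus three computed,
non-inherent convenience attributes (``name_length_pairs``,
``sorted_name_length_pairs``, ``sorted_sequences``).

Encoding proceeds in five steps:

1. collate the records into the canonical object representation;
2. canonicalize the value of each attribute individually (RFC 8785);
3. digest each canonicalized value (sha512t24u) — the *level 1* digests;
4. canonicalize the map of inherent attribute names to level-1 digests;
5. digest that map — the *level 0* ("top-level") digest.

Only inherent attributes contribute to level 0; non-inherent attributes
are digested into level 1 for retrieval and filtering but are excluded
from identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .digest import canonicalize_json, sha512t24u

__all__ = [
    "SequenceRecord",
    "CanonicalSeqcol",
    "AttributeSpec",
    "SeqcolSchema",
    "DigestedSeqcol",
    "Violation",
    "SchemaViolationError",
    "default_schema",
    "build_canonical",
    "compute_name_length_pairs",
    "compute_sorted_name_length_pairs",
    "compute_sorted_sequences",
    "encode",
    "validate",
    "COMPUTED_ATTRIBUTES",
]

#: Non-inherent attributes derivable from the three primary arrays.
COMPUTED_ATTRIBUTES = ("name_length_pairs", "sorted_name_length_pairs", "sorted_sequences")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence: its name, residue count, and content digest.

    ``sequence_digest`` may be ``None`` for coordinate-system-only
    collections (supported under a custom schema where ``sequences`` is
    not required).
    """

    name: str
    length: int
    sequence_digest: str | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative length for {self.name!r}: {self.length}")


@dataclass(frozen=True)
class AttributeSpec:
    required: bool = False
    collated: bool = False
    inherent: bool = False


@dataclass
class SeqcolSchema:
    """Declares collection attributes and their inherent/non-inherent status."""

    attributes: dict[str, AttributeSpec]
    name: str = "seqcol"

    def __post_init__(self) -> None:
        if not any(spec.inherent for spec in self.attributes.values()):
            raise ValueError("schema must declare at least one inherent attribute")

    @property
    def inherent(self) -> list[str]:
        return [a for a, s in self.attributes.items() if s.inherent]

    @property
    def required(self) -> list[str]:
        return [a for a, s in self.attributes.items() if s.required]

    @property
    def collated(self) -> list[str]:
        return [a for a, s in self.attributes.items() if s.collated]

    def to_dict(self) -> dict[str, Any]:
        """JSON-Schema-flavoured document with custom keyword lists."""
        return {
            "description": self.name,
            "type": "object",
            "properties": {a: {"type": "array"} for a in self.attributes},
            "required": self.required,
            "collated": self.collated,
            "inherent": self.inherent,
        }

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "SeqcolSchema":
        ga4gh = doc.get("ga4gh", {})
        inherent = set(doc.get("inherent", ga4gh.get("inherent", [])))
        required = set(doc.get("required", []))
        collated = set(doc.get("collated", []))
        names = set(doc.get("properties", {})) | inherent | required | collated
        return cls(
            attributes={
                a: AttributeSpec(
                    required=a in required,
                    collated=a in collated,
                    inherent=a in inherent,
                )
                for a in sorted(names)
            },
            name=doc.get("description", "seqcol"),
        )

    @classmethod
    def from_file(cls, path: str) -> "SeqcolSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_schema() -> SeqcolSchema:
    """names/lengths/sequences inherent and required; computed attributes non-inherent."""
    return SeqcolSchema(
        attributes={
            "names": AttributeSpec(required=True, collated=True, inherent=True),
            "lengths": AttributeSpec(required=True, collated=True, inherent=True),
            "sequences": AttributeSpec(required=True, collated=True, inherent=True),
            "name_length_pairs": AttributeSpec(collated=True),
            "sorted_name_length_pairs": AttributeSpec(),
            "sorted_sequences": AttributeSpec(),
        }
    )


@dataclass
class CanonicalSeqcol:
    """The collated names/lengths/sequences arrays identity is computed from."""

    names: list[str]
    lengths: list[int]
    sequences: list[str] | None = None
    extras: dict[str, list[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(self.lengths) != n or (
            self.sequences is not None and len(self.sequences) != n
        ):
            raise ValueError("collated arrays must have identical length")
        if n == 0:
            warnings.warn("empty sequence collection", stacklevel=3)

    def __len__(self) -> int:
        return len(self.names)

    def attribute_values(self) -> dict[str, list[Any]]:
        out: dict[str, list[Any]] = {"names": self.names, "lengths": self.lengths}
        if self.sequences is not None:
            out["sequences"] = self.sequences
        out.update(self.extras)
        return out


def build_canonical(records: Iterable[SequenceRecord]) -> CanonicalSeqcol:
    """Collate an ordered list of records into parallel arrays.

    Order is preserved: index ``i`` of every array derives from
    ``records[i]``. If every record lacks a sequence digest the
    ``sequences`` array is absent (coordinate-system-only collection);
    a mixture of present and absent digests is rejected.
    """
    records = list(records)
    names = [r.name for r in records]
    lengths = [r.length for r in records]
    digests = [r.sequence_digest for r in records]
    if records and all(d is None for d in digests):
        return CanonicalSeqcol(names=names, lengths=lengths, sequences=None)
    if any(d is None for d in digests):
        raise ValueError("mixed presence of sequence digests across records")
    return CanonicalSeqcol(names=names, lengths=lengths, sequences=list(digests))


def compute_name_length_pairs(c: CanonicalSeqcol) -> list[dict[str, Any]]:
    """Collection-order array of ``{"length": ..., "name": ...}`` objects."""
    return [{"length": l, "name": n} for n, l in zip(c.names, c.lengths)]


def compute_sorted_name_length_pairs(c: CanonicalSeqcol) -> list[str]:
    """Order-invariant coordinate-system identifier material.

    Each (name, length) pair is canonicalized and digested individually;
    the digest strings are then sorted bytewise, so the result depends
    only on the multiset of pairs, not on sequence order.
    """
    return sorted(
        sha512t24u(canonicalize_json(pair)) for pair in compute_name_length_pairs(c)
    )


def compute_sorted_sequences(c: CanonicalSeqcol) -> list[str]:
    if c.sequences is None:
        raise ValueError("collection has no sequences attribute")
    return sorted(c.sequences)


@dataclass
class DigestedSeqcol:
    """Levels 0/1/2 views of an encoded collection."""

    level2: dict[str, Any]
    level1: dict[str, str]
    level0: str
    schema: SeqcolSchema = field(default_factory=default_schema)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.level2.get("names", ()))

    def representation(self, level: int) -> Any:
        if level == 0:
            return self.level0
        if level == 1:
            return dict(self.level1)
        if level == 2:
            return dict(self.level2)
        raise ValueError(f"unknown representation level: {level}")


@dataclass(frozen=True)
class Violation:
    attribute: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.severity}] {self.attribute}: {self.message}"


class SchemaViolationError(ValueError):
    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__(
            "; ".join(f"{v.attribute}: {v.message}" for v in self.violations)
        )


def validate(level2: Mapping[str, Any], schema: SeqcolSchema) -> list[Violation]:
    """Check a level-2 object against a schema; violations are data, not exceptions."""
    violations: list[Violation] = []
    for attr in schema.required:
        if attr in COMPUTED_ATTRIBUTES:
            continue  # computable on demand
        if attr not in level2:
            violations.append(Violation(attr, "required attribute missing"))
    lengths = {
        a: len(level2[a])
        for a in schema.collated
        if a in level2 and isinstance(level2[a], (list, tuple))
    }
    if len(set(lengths.values())) > 1:
        detail = ", ".join(f"{a}={n}" for a, n in sorted(lengths.items()))
        violations.append(
            Violation("/".join(sorted(lengths)), f"collated arrays differ in length ({detail})")
        )
    names = level2.get("names")
    if names is not None:
        if any(not isinstance(n, str) or not n for n in names):
            violations.append(Violation("names", "names must be non-empty strings"))
        if len(set(names)) != len(names):
            violations.append(
                Violation("names", "duplicate names within collection", severity="warning")
            )
    for l in level2.get("lengths", ()):
        if not isinstance(l, int) or isinstance(l, bool) or l < 0:
            violations.append(Violation("lengths", f"invalid length {l!r}"))
            break
    return violations


def _as_canonical(obj: CanonicalSeqcol | Mapping[str, Any]) -> CanonicalSeqcol:
    if isinstance(obj, CanonicalSeqcol):
        return obj
    extras = {
        k: list(v)
        for k, v in obj.items()
        if k not in ("names", "lengths", "sequences") and k not in COMPUTED_ATTRIBUTES
    }
    return CanonicalSeqcol(
        names=list(obj["names"]),
        lengths=list(obj["lengths"]),
        sequences=list(obj["sequences"]) if "sequences" in obj else None,
        extras=extras,
    )


def encode(
    c: CanonicalSeqcol | Mapping[str, Any],
    schema: SeqcolSchema | None = None,
) -> DigestedSeqcol:
    """Run the five-step encoding, producing levels 2, 1, and 0.

    Raises :class:`SchemaViolationError` on error-severity violations;
    warning-severity violations (e.g. duplicate names) are recorded in
    the result metadata.
    """
    schema = schema or default_schema()
    if not isinstance(c, CanonicalSeqcol):
        pre = [v for v in validate(c, schema) if v.severity == "error"]
        if pre:
            raise SchemaViolationError(pre)
    canonical = _as_canonical(c)

    level2: dict[str, Any] = dict(canonical.attribute_values())
    for attr in COMPUTED_ATTRIBUTES:
        if attr not in schema.attributes:
            continue
        if attr == "name_length_pairs":
            level2[attr] = compute_name_length_pairs(canonical)
        elif attr == "sorted_name_length_pairs":
            level2[attr] = compute_sorted_name_length_pairs(canonical)
        elif attr == "sorted_sequences" and canonical.sequences is not None:
            level2[attr] = compute_sorted_sequences(canonical)

    violations = validate(level2, schema)
    errors = [v for v in violations if v.severity == "error"]
    if errors:
        raise SchemaViolationError(errors)

    level1 = {
        attr: sha512t24u(canonicalize_json(value)) for attr, value in level2.items()
    }
    inherent_map = {a: level1[a] for a in schema.inherent if a in level1}
    level0 = sha512t24u(canonicalize_json(inherent_map))
    metadata = {"warnings": [str(v) for v in violations if v.severity == "warning"]}
    return DigestedSeqcol(
        level2=level2, level1=level1, level0=level0, schema=schema, metadata=metadata
    )
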