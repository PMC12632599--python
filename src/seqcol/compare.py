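"""Collection comparison: shared-element accounting, similarity scores,
relationship classification, and human-readable interpretation.

Element counts use unique elements (duplicates collapsed), matching the
set semantics of Jaccard and overlap-proportion scores; the shared-order
flag is reported as ``None`` (undefined) when duplicates survive in the
filtered arrays or fewer than two elements are shared. Scores are exact
:class:`fractions.Fraction` values internally so subset boundaries
(``opa == 1``) never depend on float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Hashable, Mapping, Sequence

from .digest import canonicalize_json
from .model import DigestedSeqcol, default_schema, encode

__all__ = [
    "ComparisonResult",
    "SimilarityScores",
    "RelationshipVerdict",
    "Observation",
    "compare",
    "jaccard",
    "overlap_proportions",
    "score_pair",
    "classify_relationship",
    "interpret",
    "RELATIONS",
]

RELATIONS = (
    "identical-as-sets",
    "a-subset-of-b",
    "b-subset-of-a",
    "partial-overlap",
    "disjoint",
)


def _as_key(element: Any) -> Hashable:
    """Hashable identity for an array element (objects via canonical JSON)."""
    if isinstance(element, (dict, list)):
        return canonicalize_json(element)
    return element


@dataclass(frozen=True)
class SimilarityScores:
    """Jaccard and overlap proportions; ``None`` marks undefined (empty side)."""

    jaccard: Fraction | None
    opa: Fraction | None
    opb: Fraction | None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "jaccard": None if self.jaccard is None else float(self.jaccard),
            "opa": None if self.opa is None else float(self.opa),
            "opb": None if self.opb is None else float(self.opb),
        }


@dataclass(frozen=True)
class RelationshipVerdict:
    attribute: str
    relation: str
    scores: SimilarityScores

    def to_dict(self) -> dict[str, Any]:
        return {
            "attribute": self.attribute,
            "relation": self.relation,
            "scores": self.scores.to_dict(),
        }


@dataclass
class ComparisonResult:
    """Outcome of comparing two collections, attribute by attribute."""

    digests: dict[str, str | None]
    attributes: dict[str, list[str]]
    array_elements: dict[str, dict[str, Any]]
    duplicates: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "digests": dict(self.digests),
            "attributes": {k: list(v) for k, v in self.attributes.items()},
            "array_elements": {
                "a": dict(self.array_elements["a"]),
                "b": dict(self.array_elements["b"]),
                "a_and_b": dict(self.array_elements["a_and_b"]),
                "a_and_b_same_order": dict(self.array_elements["a_and_b_same_order"]),
            },
        }

    def swapped(self) -> "ComparisonResult":
        """The same result with the a/b labels exchanged."""
        return ComparisonResult(
            digests={"a": self.digests["b"], "b": self.digests["a"]},
            attributes={
                "a_only": list(self.attributes["b_only"]),
                "b_only": list(self.attributes["a_only"]),
                "a_and_b": list(self.attributes["a_and_b"]),
            },
            array_elements={
                "a": dict(self.array_elements["b"]),
                "b": dict(self.array_elements["a"]),
                "a_and_b": dict(self.array_elements["a_and_b"]),
                "a_and_b_same_order": dict(self.array_elements["a_and_b_same_order"]),
            },
            duplicates={
                "a": dict(self.duplicates.get("b", {})),
                "b": dict(self.duplicates.get("a", {})),
            },
        )


def jaccard(x: Sequence[Any], y: Sequence[Any]) -> Fraction | None:
    """|unique(x) ∩ unique(y)| / |unique(x) ∪ unique(y)|; None if both empty."""
    sx = {_as_key(e) for e in x}
    sy = {_as_key(e) for e in y}
    union = sx | sy
    if not union:
        return None
    return Fraction(len(sx & sy), len(union))


def overlap_proportions(
    x: Sequence[Any], y: Sequence[Any]
) -> tuple[Fraction | None, Fraction | None]:
    """Intersection size over each side's unique-element count; None per empty side."""
    sx = {_as_key(e) for e in x}
    sy = {_as_key(e) for e in y}
    inter = len(sx & sy)
    opa = Fraction(inter, len(sx)) if sx else None
    opb = Fraction(inter, len(sy)) if sy else None
    return opa, opb


def score_pair(x: Sequence[Any], y: Sequence[Any], attribute: str = "") -> SimilarityScores:
    opa, opb = overlap_proportions(x, y)
    return SimilarityScores(jaccard=jaccard(x, y), opa=opa, opb=opb)


def classify_relationship(
    s: SimilarityScores, attribute: str = ""
) -> RelationshipVerdict:
    """Map (jaccard, opa, opb) to a set relationship per the decision table.

    Requires scores computed from one pair of non-empty element lists;
    inconsistent score combinations raise ``ValueError``.
    """
    j, opa, opb = s.jaccard, s.opa, s.opb
    if j is None or opa is None or opb is None:
        raise ValueError("relationship undefined for empty element lists")
    if not (j <= opa and j <= opb):
        raise ValueError(f"inconsistent scores: jaccard {j} exceeds an overlap proportion")
    if (j == 1) != (opa == 1 and opb == 1):
        raise ValueError("inconsistent scores at the identity boundary")
    if j == 1:
        relation = "identical-as-sets"
    elif opa == 1:
        relation = "a-subset-of-b"
    elif opb == 1:
        relation = "b-subset-of-a"
    elif j == 0:
        relation = "disjoint"
    else:
        relation = "partial-overlap"
    return RelationshipVerdict(attribute=attribute, relation=relation, scores=s)


def _level2(obj: DigestedSeqcol | Mapping[str, Any]) -> tuple[dict[str, Any], str | None]:
    if isinstance(obj, DigestedSeqcol):
        return obj.level2, obj.level0
    # Ad-hoc level-2 object: compute missing derived attributes and the
    # digest under the default schema so digest-bearing fields are filled.
    digested = encode(obj, default_schema())
    level2 = dict(digested.level2)
    # keep only attributes the caller supplied, plus computed ones present
    return level2, digested.level0


def _same_order(a: list[Any], b: list[Any]) -> bool | None:
    keys_a = [_as_key(e) for e in a]
    keys_b = [_as_key(e) for e in b]
    shared = set(keys_a) & set(keys_b)
    fa = [k for k in keys_a if k in shared]
    fb = [k for k in keys_b if k in shared]
    if len(fa) != len(set(fa)) or len(fb) != len(set(fb)):
        return None  # duplicates make order ill-defined
    if len(shared) < 2:
        return None
    return fa == fb


def compare(
    a: DigestedSeqcol | Mapping[str, Any],
    b: DigestedSeqcol | Mapping[str, Any],
) -> ComparisonResult:
    """The standard's comparison function.

    Partitions attribute names into a-only/b-only/shared; for each shared
    list-valued attribute reports unique-element counts on each side and
    in the intersection, and whether the shared elements appear in the
    same relative order. Symmetric: ``compare(b, a)`` equals
    ``compare(a, b).swapped()``.
    """
    l2a, d_a = _level2(a)
    l2b, d_b = _level2(b)
    attrs_a = {k for k, v in l2a.items() if isinstance(v, (list, tuple))}
    attrs_b = {k for k, v in l2b.items() if isinstance(v, (list, tuple))}
    shared = sorted(attrs_a & attrs_b)

    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    counts_ab: dict[str, int] = {}
    same_order: dict[str, bool | None] = {}
    dup_a: dict[str, bool] = {}
    dup_b: dict[str, bool] = {}
    for attr in shared:
        xa, xb = list(l2a[attr]), list(l2b[attr])
        ka = [_as_key(e) for e in xa]
        kb = [_as_key(e) for e in xb]
        sa, sb = set(ka), set(kb)
        counts_a[attr] = len(sa)
        counts_b[attr] = len(sb)
        counts_ab[attr] = len(sa & sb)
        same_order[attr] = _same_order(xa, xb)
        dup_a[attr] = len(ka) != len(sa)
        dup_b[attr] = len(kb) != len(sb)

    return ComparisonResult(
        digests={"a": d_a, "b": d_b},
        attributes={
            "a_only": sorted(attrs_a - attrs_b),
            "b_only": sorted(attrs_b - attrs_a),
            "a_and_b": shared,
        },
        array_elements={
            "a": counts_a,
            "b": counts_b,
            "a_and_b": counts_ab,
            "a_and_b_same_order": same_order,
        },
        duplicates={"a": dup_a, "b": dup_b},
    )


@dataclass(frozen=True)
class Observation:
    attribute: str
    relation: str
    text: str

    def to_dict(self) -> dict[str, str]:
        return {"attribute": self.attribute, "relation": self.relation, "text": self.text}


def _attr_relation(r: ComparisonResult, attr: str) -> str:
    na = r.array_elements["a"][attr]
    nb = r.array_elements["b"][attr]
    nab = r.array_elements["a_and_b"][attr]
    if na == 0 and nb == 0:
        return "undefined"
    if nab == na == nb:
        return "identical-as-sets"
    if nab == na:
        return "a-subset-of-b"
    if nab == nb:
        return "b-subset-of-a"
    if nab == 0:
        return "disjoint"
    return "partial-overlap"


def interpret(r: ComparisonResult) -> list[Observation]:
    """Plain-language reading of a comparison result.

    Emits one observation per shared attribute, plus cross-attribute
    observations for the named compatibility levels: exact identity,
    order-relaxed identity, name-relaxed identity (matching sequences
    under different names), subsets, and shared coordinate systems.
    """
    obs: list[Observation] = []
    order = r.array_elements["a_and_b_same_order"]
    for attr in r.attributes["a_and_b"]:
        rel = _attr_relation(r, attr)
        same = order.get(attr)
        if rel == "identical-as-sets":
            if same is True:
                text = f"Collections carry identical {attr} in the same order."
            elif same is False:
                text = (
                    f"Collections carry identical {attr} in a different order "
                    "(order-relaxed identity)."
                )
                rel = "order-relaxed-identity"
            else:
                text = f"Collections carry identical {attr}; element order is undefined."
        elif rel == "a-subset-of-b":
            text = f"Collection A's {attr} are a subset of collection B's."
        elif rel == "b-subset-of-a":
            text = f"Collection B's {attr} are a subset of collection A's."
        elif rel == "disjoint":
            text = f"Collections share no {attr}."
        elif rel == "partial-overlap":
            nab = r.array_elements["a_and_b"][attr]
            text = f"Collections share {nab} of their {attr}."
        else:
            text = f"Both collections have empty {attr}."
        obs.append(Observation(attribute=attr, relation=rel, text=text))

    rels = {o.attribute: o.relation for o in obs}
    if all(
        rels.get(a) == "identical-as-sets" and order.get(a) is not False
        for a in ("names", "lengths", "sequences")
        if a in rels
    ) and "sequences" in rels:
        obs.append(
            Observation(
                attribute="*",
                relation="identical",
                text="The collections are identical.",
            )
        )
    elif (
        rels.get("sequences") == "identical-as-sets"
        and rels.get("names") in ("disjoint", "partial-overlap")
    ):
        obs.append(
            Observation(
                attribute="*",
                relation="name-relaxed-identity",
                text=(
                    "The collections contain matching sequences under different "
                    "names (name-relaxed identity)."
                ),
            )
        )
    if rels.get("name_length_pairs") in ("identical-as-sets", "order-relaxed-identity"):
        obs.append(
            Observation(
                attribute="name_length_pairs",
                relation="shared-coordinate-system",
                text="The collections share a coordinate system (same names and lengths).",
            )
        )
    return obs
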