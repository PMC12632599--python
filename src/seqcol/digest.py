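"""Canonical JSON serialization and the truncated-SHA512 digest primitive.

Every identifier in this package is built from two operations:

1. :func:`canonicalize_json` — serialize a JSON value to the unique byte
   string defined by the RFC 8785 JSON Canonicalization Scheme (JCS):
   no insignificant whitespace, object members sorted by UTF-16 code
   units, strings escaped minimally, and numbers rendered with the
   ECMAScript shortest round-trip algorithm.

2. :func:`sha512t24u` — SHA-512 truncated to its first 24 bytes and
   base64url-encoded without padding, yielding a fixed 32-character
   digest over the base64url alphabet ``[A-Za-z0-9_-]``.

Sequence residues are digested after uppercasing (:func:`sequence_digest`),
so soft-masked and unmasked versions of the same residues share a digest
while hard-masking (N substitution) changes it.
"""

from __future__ import annotations

import base64
import hashlib
import math
import re
from typing import Any

__all__ = [
    "CanonicalizationError",
    "canonicalize_json",
    "sha512t24u",
    "sequence_digest",
    "prefixed_identifier",
    "split_identifier",
    "DIGEST_RE",
    "SEQUENCE_PREFIX",
]

#: Regular expression every digest value must match.
DIGEST_RE = re.compile(r"^[A-Za-z0-9_-]{32}$")

#: Default namespace prefix for per-sequence digests.
SEQUENCE_PREFIX = "SQ"

# Largest integer exactly representable as an IEEE-754 double.
_MAX_SAFE_INT = 2**53 - 1

# Short escapes mandated by the canonicalization scheme.
_ESCAPES = {
    "\\": "\\\\",
    '"': '\\"',
    "\b": "\\b",
    "\t": "\\t",
    "\n": "\\n",
    "\f": "\\f",
    "\r": "\\r",
}


class CanonicalizationError(ValueError):
    """Raised for values with no canonical JSON serialization."""


def _serialize_string(s: str) -> str:
    out = ['"']
    for ch in s:
        esc = _ESCAPES.get(ch)
        if esc is not None:
            out.append(esc)
        elif ch < "\x20":
            out.append(f"\\u{ord(ch):04x}")
        else:
            out.append(ch)
    out.append('"')
    return "".join(out)


def _serialize_float(x: float) -> str:
    # ECMAScript Number::toString for doubles: shortest round-trip digits,
    # fixed notation for decimal exponents in (-7, 21], scientific otherwise.
    if math.isnan(x) or math.isinf(x):
        raise CanonicalizationError("NaN and Infinity are not serializable")
    if x == 0:
        return "0"
    sign = "-" if x < 0 else ""
    mant = repr(abs(x))  # shortest repr that round-trips
    if "e" in mant or "E" in mant:
        m, _, e = mant.lower().partition("e")
        exp10 = int(e)
    else:
        m, exp10 = mant, 0
    if "." in m:
        int_part, frac_part = m.split(".")
    else:
        int_part, frac_part = m, ""
    digits = (int_part + frac_part).lstrip("0")
    # n: position of the decimal point relative to the digit string,
    # i.e. value == 0.digits * 10**n
    n = len(int_part.lstrip("0")) + exp10 if int_part.lstrip("0") else exp10 - (
        len(frac_part) - len(frac_part.lstrip("0"))
    )
    digits = digits.rstrip("0")
    k = len(digits)
    if k <= n <= 21:
        return sign + digits + "0" * (n - k)
    if 0 < n <= 21:
        return sign + digits[:n] + "." + digits[n:]
    if -6 < n <= 0:
        return sign + "0." + "0" * (-n) + digits
    # scientific notation
    mantissa = digits[0] + ("." + digits[1:] if k > 1 else "")
    exp = n - 1
    return f"{sign}{mantissa}e{'+' if exp >= 0 else '-'}{abs(exp)}"


def _serialize(value: Any, out: list[str]) -> None:
    if value is None:
        out.append("null")
    elif value is True:
        out.append("true")
    elif value is False:
        out.append("false")
    elif isinstance(value, str):
        out.append(_serialize_string(value))
    elif isinstance(value, int):
        if abs(value) > _MAX_SAFE_INT:
            raise CanonicalizationError(
                f"integer {value} exceeds the IEEE-754 safe range"
            )
        out.append(str(value))
    elif isinstance(value, float):
        out.append(_serialize_float(value))
    elif isinstance(value, (list, tuple)):
        out.append("[")
        for i, item in enumerate(value):
            if i:
                out.append(",")
            _serialize(item, out)
        out.append("]")
    elif isinstance(value, dict):
        out.append("{")
        # Member ordering: sort keys on their UTF-16 code unit sequence.
        keys = sorted(value, key=lambda k: k.encode("utf-16-be"))
        for i, key in enumerate(keys):
            if not isinstance(key, str):
                raise CanonicalizationError(f"object key {key!r} is not a string")
            if i:
                out.append(",")
            out.append(_serialize_string(key))
            out.append(":")
            _serialize(value[key], out)
        out.append("}")
    else:
        raise CanonicalizationError(
            f"value of type {type(value).__name__} is not JSON-serializable"
        )


def canonicalize_json(value: Any) -> bytes:
    """Serialize *value* to its unique RFC 8785 canonical form as UTF-8 bytes.

    Idempotent: parsing the output and canonicalizing again reproduces the
    same bytes. Raises :class:`CanonicalizationError` for non-finite floats,
    integers outside the IEEE-754 safe range, non-string keys, or values
    that are not JSON.
    """
    out: list[str] = []
    _serialize(value, out)
    return "".join(out).encode("utf-8")


def sha512t24u(data: bytes) -> str:
    """Digest bytes: SHA-512, truncated to 24 bytes, base64url, no padding.

    Always returns exactly 32 characters from ``[A-Za-z0-9_-]``.
    """
    return base64.urlsafe_b64encode(hashlib.sha512(data).digest()[:24]).decode(
        "ascii"
    )


def sequence_digest(sequence: str) -> str:
    """Digest of a residue string, uppercased before hashing.

    Soft-masked (lowercase) and unmasked residues therefore share one
    digest; hard-masked (N-substituted) residues do not. The empty
    sequence digests the empty byte string.
    """
    return sha512t24u(sequence.upper().encode("utf-8"))


def prefixed_identifier(digest: str, prefix: str = SEQUENCE_PREFIX) -> str:
    """Namespace a digest as ``prefix + "." + digest``."""
    if not prefix or "." in prefix:
        raise ValueError(f"prefix must be a non-empty token without '.': {prefix!r}")
    return f"{prefix}.{digest}"


def split_identifier(identifier: str) -> tuple[str | None, str]:
    """Split ``"SQ.<digest>"`` into ``("SQ", "<digest>")``; no prefix -> None."""
    prefix, sep, rest = identifier.partition(".")
    if not sep:
        return None, identifier
    return prefix, rest
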