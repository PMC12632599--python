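"""Retrieval and comparison HTTP API over a pluggable collection store.

The service core (:class:`SeqcolService.handle`) is a pure function from
(method, path, query, body) to (status, JSON body), wrapped by a thin
``http.server`` layer so no web framework is required. Stores keep each
attribute value once, keyed by its attribute digest, so two collections
sharing an attribute share storage; ``add`` is idempotent.

Endpoints:

- ``GET /service-info`` — service metadata, including the advertised schema.
- ``GET /collection/{digest}?level=0|1|2`` — retrieve a stored collection.
- ``GET /comparison/{a}/{b}`` / ``POST /comparison/{a}`` — compare stored
  collections, or a POSTed ad-hoc level-2 object against a stored one.
- ``GET /list/collections?page&page_size&{attr}={digest}`` — paged digest
  list, filterable by attribute digest.
- ``GET /attribute/collection/{attr}/{digest}`` — one attribute's value.

Write access is deliberately not exposed over HTTP; collections are bulk
loaded via the CLI or the store API.
"""

from __future__ import annotations

import json
import sqlite3
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Iterator
from urllib.parse import parse_qs, urlparse

from .compare import compare
from .digest import DIGEST_RE
from .model import DigestedSeqcol, SchemaViolationError, SeqcolSchema, default_schema, encode

__all__ = [
    "CollectionStore",
    "InMemoryStore",
    "SqliteStore",
    "SeqcolService",
    "create_server",
    "MAX_PAGE_SIZE",
]

MAX_PAGE_SIZE = 1000
SPEC_VERSION = "1.0.0"


class CollectionStore:
    """Contract for collection storage backends."""

    def add(self, collection: DigestedSeqcol) -> str:
        raise NotImplementedError

    def level1(self, level0: str) -> dict[str, str]:
        raise NotImplementedError

    def attribute(self, attribute: str, digest: str) -> Any:
        raise NotImplementedError

    def digests(self) -> Iterator[str]:
        """All stored top-level digests in insertion order."""
        raise NotImplementedError

    def n_attribute_values(self) -> int:
        """Number of distinct attribute values held (for dedup accounting)."""
        raise NotImplementedError

    # -- derived helpers -----------------------------------------------------

    def __contains__(self, level0: str) -> bool:
        try:
            self.level1(level0)
            return True
        except KeyError:
            return False

    def __len__(self) -> int:
        return sum(1 for _ in self.digests())

    def get(self, level0: str, level: int = 2) -> Any:
        l1 = self.level1(level0)
        if level == 0:
            return level0
        if level == 1:
            return dict(l1)
        if level == 2:
            return {attr: self.attribute(attr, d) for attr, d in l1.items()}
        raise ValueError(f"unknown representation level: {level}")

    def list(
        self, page: int = 0, page_size: int = 100, filters: dict[str, str] | None = None
    ) -> tuple[list[str], int]:
        items = list(self.digests())
        for attr, digest in (filters or {}).items():
            items = [d for d in items if self.level1(d).get(attr) == digest]
        total = len(items)
        start = page * page_size
        return items[start : start + page_size], total


class InMemoryStore(CollectionStore):
    def __init__(self) -> None:
        self._level1: dict[str, dict[str, str]] = {}
        self._values: dict[tuple[str, str], Any] = {}

    def add(self, collection: DigestedSeqcol) -> str:
        level0 = collection.level0
        if level0 not in self._level1:
            self._level1[level0] = dict(collection.level1)
            for attr, digest in collection.level1.items():
                self._values.setdefault((attr, digest), collection.level2[attr])
        return level0

    def level1(self, level0: str) -> dict[str, str]:
        return self._level1[level0]

    def attribute(self, attribute: str, digest: str) -> Any:
        return self._values[(attribute, digest)]

    def digests(self) -> Iterator[str]:
        return iter(self._level1)

    def n_attribute_values(self) -> int:
        return len(self._values)


class SqliteStore(CollectionStore):
    """Single-file relational backend with the same dedup semantics."""

    def __init__(self, path: str = ":memory:") -> None:
        self._db = sqlite3.connect(path, check_same_thread=False)
        self._lock = threading.Lock()
        with self._lock, self._db:
            self._db.execute(
                "CREATE TABLE IF NOT EXISTS collections ("
                " level0 TEXT PRIMARY KEY, level1 TEXT NOT NULL)"
            )
            self._db.execute(
                "CREATE TABLE IF NOT EXISTS attribute_values ("
                " attribute TEXT, digest TEXT, value TEXT NOT NULL,"
                " PRIMARY KEY (attribute, digest))"
            )

    def add(self, collection: DigestedSeqcol) -> str:
        with self._lock, self._db:
            self._db.execute(
                "INSERT OR IGNORE INTO collections (level0, level1) VALUES (?, ?)",
                (collection.level0, json.dumps(collection.level1)),
            )
            for attr, digest in collection.level1.items():
                self._db.execute(
                    "INSERT OR IGNORE INTO attribute_values (attribute, digest, value)"
                    " VALUES (?, ?, ?)",
                    (attr, digest, json.dumps(collection.level2[attr])),
                )
        return collection.level0

    def level1(self, level0: str) -> dict[str, str]:
        with self._lock:
            row = self._db.execute(
                "SELECT level1 FROM collections WHERE level0 = ?", (level0,)
            ).fetchone()
        if row is None:
            raise KeyError(level0)
        return json.loads(row[0])

    def attribute(self, attribute: str, digest: str) -> Any:
        with self._lock:
            row = self._db.execute(
                "SELECT value FROM attribute_values WHERE attribute = ? AND digest = ?",
                (attribute, digest),
            ).fetchone()
        if row is None:
            raise KeyError((attribute, digest))
        return json.loads(row[0])

    def digests(self) -> Iterator[str]:
        with self._lock:
            rows = self._db.execute(
                "SELECT level0 FROM collections ORDER BY rowid"
            ).fetchall()
        return iter(r[0] for r in rows)

    def n_attribute_values(self) -> int:
        with self._lock:
            (n,) = self._db.execute("SELECT COUNT(*) FROM attribute_values").fetchone()
        return n


class _HTTPError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


class SeqcolService:
    """Framework-free request handling for the API endpoints."""

    def __init__(
        self,
        store: CollectionStore | None = None,
        schema: SeqcolSchema | None = None,
        service_id: str = "org.seqcol.demo",
        name: str = "seqcol reference service",
    ) -> None:
        self.store = store if store is not None else InMemoryStore()
        self.schema = schema or default_schema()
        self.service_id = service_id
        self.name = name

    # -- endpoint implementations -------------------------------------------

    def service_info(self) -> dict[str, Any]:
        return {
            "id": self.service_id,
            "name": self.name,
            "type": {"group": "org.ga4gh", "artifact": "refget-seqcol", "version": SPEC_VERSION},
            "seqcol": {"schema": self.schema.to_dict()},
        }

    def _require_digest(self, digest: str) -> None:
        if not DIGEST_RE.match(digest):
            raise _HTTPError(400, f"malformed digest: {digest!r}")

    def _stored(self, digest: str) -> DigestedSeqcol:
        self._require_digest(digest)
        try:
            level2 = self.store.get(digest, 2)
        except KeyError:
            raise _HTTPError(404, f"collection not found: {digest}")
        return DigestedSeqcol(
            level2=level2, level1=self.store.get(digest, 1), level0=digest, schema=self.schema
        )

    def collection(self, digest: str, level: int = 2) -> Any:
        self._require_digest(digest)
        if level not in (0, 1, 2):
            raise _HTTPError(400, f"unknown level: {level}")
        if digest not in self.store:
            raise _HTTPError(404, f"collection not found: {digest}")
        return self.store.get(digest, level)

    def comparison(self, digest_a: str, digest_b: str) -> dict[str, Any]:
        a = self._stored(digest_a)
        b = self._stored(digest_b)
        return compare(a, b).to_dict()

    def comparison_post(self, digest_a: str, body: Any) -> dict[str, Any]:
        a = self._stored(digest_a)
        if not isinstance(body, dict):
            raise _HTTPError(422, "comparison body must be a level-2 JSON object")
        try:
            b = encode(body, self.schema)
        except (SchemaViolationError, KeyError, TypeError, ValueError) as exc:
            raise _HTTPError(422, f"invalid collection body: {exc}")
        return compare(a, b).to_dict()

    def list_collections(
        self, page: int = 0, page_size: int = 100, filters: dict[str, str] | None = None
    ) -> dict[str, Any]:
        if page < 0 or not 1 <= page_size <= MAX_PAGE_SIZE:
            raise _HTTPError(400, "bad paging parameters")
        for attr in filters or {}:
            if attr not in self.schema.attributes:
                raise _HTTPError(400, f"unknown filter attribute: {attr!r}")
        items, total = self.store.list(page, page_size, filters)
        return {
            "results": items,
            "pagination": {"page": page, "page_size": page_size, "total": total},
        }

    def attribute(self, attribute: str, digest: str) -> Any:
        if attribute not in self.schema.attributes:
            raise _HTTPError(404, f"unknown attribute: {attribute!r}")
        self._require_digest(digest)
        try:
            return self.store.attribute(attribute, digest)
        except KeyError:
            raise _HTTPError(404, f"no {attribute} value with digest {digest}")

    # -- dispatch ------------------------------------------------------------

    def handle(
        self, method: str, path: str, query: dict[str, str] | None = None, body: Any = None
    ) -> tuple[int, Any]:
        """Route a request; returns (HTTP status, JSON-serializable body)."""
        query = dict(query or {})
        parts = [p for p in path.split("/") if p]
        try:
            if method == "GET" and parts == ["service-info"]:
                return 200, self.service_info()
            if method == "GET" and len(parts) == 2 and parts[0] == "collection":
                level = query.pop("level", "2")
                if level not in ("0", "1", "2"):
                    raise _HTTPError(400, f"unknown level: {level!r}")
                return 200, self.collection(parts[1], int(level))
            if method == "GET" and len(parts) == 3 and parts[0] == "comparison":
                return 200, self.comparison(parts[1], parts[2])
            if method == "POST" and len(parts) == 2 and parts[0] == "comparison":
                return 200, self.comparison_post(parts[1], body)
            if method == "GET" and parts == ["list", "collections"]:
                try:
                    page = int(query.pop("page", "0"))
                    page_size = int(query.pop("page_size", "100"))
                except ValueError:
                    raise _HTTPError(400, "bad paging parameters")
                return 200, self.list_collections(page, page_size, query)
            if method == "GET" and len(parts) == 4 and parts[:2] == ["attribute", "collection"]:
                return 200, self.attribute(parts[2], parts[3])
            raise _HTTPError(404, f"no such endpoint: {method} {path}")
        except _HTTPError as exc:
            return exc.status, {"error": exc.message, "status": exc.status}


def create_server(
    service: SeqcolService, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Wrap a service in a threading stdlib HTTP server (port 0 = ephemeral)."""

    class Handler(BaseHTTPRequestHandler):
        def _respond(self, method: str) -> None:
            parsed = urlparse(self.path)
            query = {k: v[0] for k, v in parse_qs(parsed.query).items()}
            body = None
            if method == "POST":
                length = int(self.headers.get("Content-Length", 0))
                raw = self.rfile.read(length)
                try:
                    body = json.loads(raw) if raw else None
                except json.JSONDecodeError:
                    self._send(422, {"error": "request body is not valid JSON", "status": 422})
                    return
            status, payload = service.handle(method, parsed.path, query, body)
            self._send(status, payload)

        def _send(self, status: int, payload: Any) -> None:
            data = json.dumps(payload).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self) -> None:  # noqa: N802 (stdlib naming)
            self._respond("GET")

        def do_POST(self) -> None:  # noqa: N802
            self._respond("POST")

        def log_message(self, fmt: str, *args: Any) -> None:  # silence per-request logs
            pass

    return ThreadingHTTPServer((host, port), Handler)
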