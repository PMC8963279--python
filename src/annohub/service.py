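"""REST service over one indexed build: annotation, query, batch and
metadata endpoints in the style of annotation-as-a-service APIs.

The HTTP layer adds nothing: every response body is a pure function of the
index and the parsed request, computed by the handlers below; the WSGI
wrapper only routes, decodes parameters and serializes JSON.  Endpoints::

    GET  /{entity}/{id}?fields=...
    GET  /query?q=...&fields=...&size=...&from=...
    POST /query                      # batch: {"ids": [...], "scopes": [...]}
    GET  /metadata
    GET  /metadata/fields
    GET  /status

All errors share one envelope: ``{"success": false, "error": ..., "code": ...}``.
"""

from __future__ import annotations

import json
import re
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Optional
from urllib.parse import parse_qs
from wsgiref.simple_server import WSGIRequestHandler, make_server

from .errors import QueryParseError, UnqueryableFieldError
from .index import (
    DEFAULT_SIZE,
    MAX_SIZE,
    NOT_FOUND,
    Index,
    execute_query,
    get_by_id,
    project_fields,
)
from .merge import BuildMetadata
from .queryast import FieldTerm, parse_query

MAX_BATCH_IDS = 1000
ENTITY_PATTERN = re.compile(r"^[a-z]+$")


@dataclass
class ServiceConfig:
    entity: str = "gene"
    port: int = 8000
    default_size: int = DEFAULT_SIZE
    cors_allow: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not ENTITY_PATTERN.match(self.entity):
            raise ValueError("entity label must match [a-z]+")


def _error(code: int, message: str) -> tuple[int, dict]:
    return code, {"success": False, "error": message, "code": code}


def _parse_fields(raw: Optional[str]) -> Optional[list[str]]:
    if raw is None or raw == "" or raw == "all":
        return None
    return [part.strip() for part in raw.split(",") if part.strip()]


class AnnotationService:
    """Handlers for one indexed build; each returns ``(status, body dict)``."""

    def __init__(
        self,
        index: Index,
        metadata: Optional[BuildMetadata] = None,
        config: Optional[ServiceConfig] = None,
    ):
        self.index = index
        self.metadata = metadata
        self.config = config or ServiceConfig()

    # -- annotation ------------------------------------------------------

    def handle_annotation(self, _id: str, fields: Optional[str] = None) -> tuple[int, dict]:
        doc = get_by_id(self.index, _id)
        if doc is NOT_FOUND:
            return _error(404, "not found")
        return 200, project_fields(doc, _parse_fields(fields))

    # -- query -----------------------------------------------------------

    def handle_query(self, params: dict[str, str]) -> tuple[int, dict]:
        q = params.get("q", "")
        try:
            size = int(params.get("size", self.config.default_size))
            from_ = int(params.get("from", 0))
        except ValueError:
            return _error(400, "size and from must be integers")
        if size > MAX_SIZE:
            return _error(400, f"size exceeds the cap of {MAX_SIZE}")
        if size < 0 or from_ < 0:
            return _error(400, "size and from must be >= 0")
        started = time.perf_counter()
        try:
            ast = parse_query(q)
            result = execute_query(
                self.index,
                ast,
                from_=from_,
                size=size,
                fields=_parse_fields(params.get("fields")),
            )
        except (QueryParseError, UnqueryableFieldError) as exc:
            return _error(400, str(exc))
        took = int((time.perf_counter() - started) * 1000)
        return 200, {
            "took": took,
            "total": result.total,
            "from": result.from_,
            "size": result.size,
            "hits": result.hits,
        }

    # -- batch -----------------------------------------------------------

    def handle_batch(self, payload: dict[str, Any]) -> tuple[int, Any]:
        ids = payload.get("ids")
        if isinstance(ids, str):
            ids = [part.strip() for part in ids.split(",") if part.strip()]
        if not isinstance(ids, list) or not ids:
            return _error(400, "ids must be a non-empty list")
        if len(ids) > MAX_BATCH_IDS:
            return _error(400, f"at most {MAX_BATCH_IDS} ids per batch")
        fields = payload.get("fields")
        if isinstance(fields, str):
            fields = _parse_fields(fields)
        scopes = payload.get("scopes") or ["_id"]
        if isinstance(scopes, str):
            scopes = [part.strip() for part in scopes.split(",") if part.strip()]

        out: list[dict] = []
        for requested in ids:
            matches: list[dict] = []
            for scope in scopes:
                if scope == "_id":
                    doc = get_by_id(self.index, requested)
                    if doc is not NOT_FOUND:
                        matches.append(doc)
                else:
                    try:
                        result = execute_query(
                            self.index,
                            FieldTerm(path=scope, value=requested),
                            from_=0,
                            size=MAX_SIZE,
                        )
                    except UnqueryableFieldError as exc:
                        return _error(400, str(exc))
                    matches.extend(result.hits)
            if not matches:
                out.append({"query": requested, "notfound": True})
                continue
            seen: set[str] = set()
            for doc in matches:
                if doc["_id"] in seen:
                    continue
                seen.add(doc["_id"])
                projected = project_fields(doc, fields)
                out.append({"query": requested, **projected})
        return 200, out

    # -- metadata --------------------------------------------------------

    def handle_metadata(self) -> tuple[int, dict]:
        body: dict[str, Any] = {"total_documents": self.index.total_documents}
        if self.metadata is not None:
            body.update(
                {
                    "build_name": self.metadata.build_name,
                    "build_version": self.metadata.build_version,
                    "sources": self.metadata.sources,
                    "root_excluded_count": self.metadata.root_excluded_count,
                }
            )
        return 200, body

    def handle_metadata_fields(self) -> tuple[int, dict]:
        return 200, self.index.mapping.flat()

    def handle_status(self) -> tuple[int, dict]:
        return 200, {"success": True, "documents": self.index.total_documents}


def make_wsgi_app(service: AnnotationService):
    """Wrap a service in a WSGI callable (routing + JSON serialization only)."""
    entity = service.config.entity

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        params = {
            key: values[-1]
            for key, values in parse_qs(environ.get("QUERY_STRING", "")).items()
        }

        if method == "GET" and path == "/status":
            status, body = service.handle_status()
        elif method == "GET" and path == "/metadata":
            status, body = service.handle_metadata()
        elif method == "GET" and path == "/metadata/fields":
            status, body = service.handle_metadata_fields()
        elif method == "GET" and path == "/query":
            status, body = service.handle_query(params)
        elif method == "POST" and path == "/query":
            try:
                length = int(environ.get("CONTENT_LENGTH") or 0)
            except ValueError:
                length = 0
            raw = environ["wsgi.input"].read(length) if length else b""
            content_type = environ.get("CONTENT_TYPE", "")
            try:
                if "json" in content_type:
                    payload = json.loads(raw.decode("utf-8")) if raw else {}
                else:
                    form = parse_qs(raw.decode("utf-8"))
                    payload = {key: values[-1] for key, values in form.items()}
            except (json.JSONDecodeError, UnicodeDecodeError):
                status, body = _error(400, "request body is not valid JSON or form data")
            else:
                status, body = service.handle_batch(payload)
        elif method == "GET":
            match = re.match(rf"^/{re.escape(entity)}/(.+)$", path)
            if match:
                status, body = service.handle_annotation(
                    match.group(1), params.get("fields")
                )
            else:
                status, body = _error(404, f"no such endpoint: {path}")
        else:
            status, body = _error(404, f"no such endpoint: {path}")

        data = json.dumps(body, ensure_ascii=False).encode("utf-8")
        reason = {200: "OK", 400: "Bad Request", 404: "Not Found"}.get(status, "")
        headers = [
            ("Content-Type", "application/json; charset=utf-8"),
            ("Content-Length", str(len(data))),
        ]
        if service.config.cors_allow:
            headers.append(
                ("Access-Control-Allow-Origin", ",".join(service.config.cors_allow))
            )
        start_response(f"{status} {reason}", headers)
        return [data]

    return app


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args):  # pragma: no cover
        pass


class ServiceServer:
    """A running HTTP server around an :class:`AnnotationService`."""

    def __init__(self, service: AnnotationService, host: str = "127.0.0.1", port: int = 0):
        self.service = service
        self.httpd = make_server(
            host, port, make_wsgi_app(service), handler_class=_QuietHandler
        )
        self.port = self.httpd.server_address[1]
        self._thread: Optional[threading.Thread] = None

    def start_background(self) -> None:
        self._thread = threading.Thread(target=self.httpd.serve_forever, daemon=True)
        self._thread.start()

    def serve_forever(self) -> None:  # pragma: no cover - interactive use
        self.httpd.serve_forever()

    def shutdown(self) -> None:
        self.httpd.shutdown()
        if self._thread:
            self._thread.join(timeout=5)
        self.httpd.server_close()
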