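"""PSICQUIC REST contract over a built index, as a stdlib WSGI application.

Routes (all HTTP GET, mirroring the standard interaction-service URL
layout)::

    /current/search/query/{miql}?format=&firstResult=&maxResults=
    /current/search/interactor/{id}      == query identifier:"{id}"
    /current/search/interaction/{id}     == query interaction_id:"{id}"
    /current/search/formats
    /current/search/version
    /current/search/properties
    /current/search/property/{key}

Supported result formats are ``tab25``/``tab26``/``tab27`` (MITAB lines of
the requested dialect, streamed), ``count`` (total matches as plain text)
and ``xgmml`` (a single chunk-streamed graph document with no record-count
cap).  ``xml25``, ``rdf`` and ``biopax`` are part of the wider REST
vocabulary but are not served here and answer 406.  Every search response
carries the total match count in the ``X-PSICQUIC-Count`` header.

The application object is a plain WSGI callable: serve it with
:func:`serve` / :func:`start_background_server`, or call it in-process for
tests.
"""

from __future__ import annotations

import threading
from typing import Dict, Iterable, Iterator, List, Optional, Tuple
from urllib.parse import parse_qs, unquote
from wsgiref.simple_server import WSGIServer, make_server, WSGIRequestHandler
from xml.sax.saxutils import quoteattr

from .mitab_model import InteractionEvidence
from .mitab_io import render_line
from .miql import MiqlSyntaxError
from .query_engine import EvaluationError, IndexedCollection, search

__all__ = ["ServiceProperties", "PsicquicApp", "stream_xgmml", "serve",
           "start_background_server", "SUPPORTED_FORMATS", "COUNT_HEADER"]

SUPPORTED_FORMATS = ("tab25", "tab26", "tab27", "count", "xgmml")
_ADVERTISED_UNSUPPORTED = ("xml25", "rdf-xml", "rdf-xml-abbrev", "rdf-n3",
                           "rdf-turtle", "biopax")
COUNT_HEADER = "X-PSICQUIC-Count"

_TAB_DIALECT = {"tab25": "2.5", "tab26": "2.6", "tab27": "2.7"}


class ServiceProperties:
    """Provider-defined service metadata exposed by the metadata routes."""

    def __init__(self, version: str = "1.3",
                 properties: Optional[Dict[str, str]] = None):
        if not version:
            raise ValueError("service version must be non-empty")
        self.version = version
        self.properties: Dict[str, str] = dict(properties or {})


class _HttpError(Exception):
    def __init__(self, status: str, body: str):
        self.status = status
        self.body = body


class PsicquicApp:
    """WSGI application answering the interaction-service REST routes."""

    def __init__(self, index: IndexedCollection, *,
                 provider_name: str = "psicquic-lite",
                 service_properties: Optional[ServiceProperties] = None):
        self.index = index
        props = {
            "psicquic.provider": provider_name,
            "psicquic.dialect": index.dialect or "2.7",
            "psicquic.record.count": str(len(index)),
        }
        if service_properties is None:
            service_properties = ServiceProperties(properties=props)
        else:
            merged = dict(props)
            merged.update(service_properties.properties)
            service_properties.properties = merged
        self.service_properties = service_properties

    # -- WSGI entry point ---------------------------------------------------

    def __call__(self, environ, start_response) -> Iterable[bytes]:
        path = unquote(environ.get("PATH_INFO", ""))
        query_string = environ.get("QUERY_STRING", "")
        params = {k: v[-1] for k, v in parse_qs(query_string).items()}
        try:
            status, headers, body = self._route(path, params)
        except _HttpError as exc:
            message = exc.body.encode("utf-8")
            start_response(exc.status, [
                ("Content-Type", "text/plain; charset=utf-8"),
                ("Content-Length", str(len(message)))])
            return [message]
        start_response(status, headers)
        return body

    def get(self, path: str, params: Optional[Dict[str, str]] = None):
        """In-process GET: returns (status, headers dict, body bytes)."""
        captured = {}

        def start_response(status, headers):
            captured["status"] = status
            captured["headers"] = dict(headers)

        query = "&".join(f"{k}={v}" for k, v in (params or {}).items())
        environ = {"PATH_INFO": path, "QUERY_STRING": query,
                   "REQUEST_METHOD": "GET"}
        body = b"".join(self(environ, start_response))
        return captured["status"], captured["headers"], body

    # -- routing ------------------------------------------------------------

    def _route(self, path: str, params: Dict[str, str]):
        prefix = "/current/search/"
        if not path.startswith(prefix):
            raise _HttpError("404 Not Found", f"no such path: {path}")
        rest = path[len(prefix):]
        if rest.startswith("query/"):
            return self._search(rest[len("query/"):], params)
        if rest.startswith("interactor/"):
            identifier = rest[len("interactor/"):]
            if not identifier:
                raise _HttpError("400 Bad Request", "empty interactor id")
            return self._search(f'identifier:"{identifier}"', params)
        if rest.startswith("interaction/"):
            identifier = rest[len("interaction/"):]
            if not identifier:
                raise _HttpError("400 Bad Request", "empty interaction id")
            return self._search(f'interaction_id:"{identifier}"', params)
        if rest == "formats":
            return self._text_response("\n".join(SUPPORTED_FORMATS) + "\n")
        if rest == "version":
            return self._text_response(self.service_properties.version)
        if rest == "properties":
            lines = [f"{key}={value}" for key, value
                     in sorted(self.service_properties.properties.items())]
            return self._text_response("\n".join(lines) + ("\n" if lines else ""))
        if rest.startswith("property/"):
            key = rest[len("property/"):]
            try:
                return self._text_response(self.service_properties.properties[key])
            except KeyError:
                raise _HttpError("404 Not Found", f"unknown property {key!r}")
        raise _HttpError("404 Not Found", f"no such operation: {rest}")

    # -- search -------------------------------------------------------------

    def _search(self, miql: str, params: Dict[str, str]):
        if not miql:
            raise _HttpError("400 Bad Request", "empty query")
        fmt = params.get("format", "tab25")
        if fmt not in SUPPORTED_FORMATS:
            known = fmt in _ADVERTISED_UNSUPPORTED
            detail = ("format defined by the REST vocabulary but not served here"
                      if known else "unknown format")
            raise _HttpError(
                "406 Not Acceptable",
                f"{detail}: {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}")
        first = _non_negative_int(params, "firstResult", 0)
        max_results = _non_negative_int(params, "maxResults", None)
        try:
            result = search(self.index, miql, first=first,
                            max_results=max_results)
        except (MiqlSyntaxError, EvaluationError) as exc:
            raise _HttpError("400 Bad Request", str(exc))
        headers = [(COUNT_HEADER, str(result.total))]
        if fmt == "count":
            body = str(result.total).encode("utf-8")
            headers += [("Content-Type", "text/plain; charset=utf-8"),
                        ("Content-Length", str(len(body)))]
            return "200 OK", headers, [body]
        if fmt == "xgmml":
            headers.append(("Content-Type", "application/xgmml+xml; charset=utf-8"))
            chunks = stream_xgmml(iter(result.records))
            return "200 OK", headers, (c.encode("utf-8") for c in chunks)
        headers.append(("Content-Type", "text/plain; charset=utf-8"))
        dialect = _TAB_DIALECT[fmt]
        body = (render_line(r, dialect, lossy=True) + "\n"
                for r in result.records)
        return "200 OK", headers, (line.encode("utf-8") for line in body)

    @staticmethod
    def _text_response(text: str):
        body = text.encode("utf-8")
        headers = [("Content-Type", "text/plain; charset=utf-8"),
                   ("Content-Length", str(len(body)))]
        return "200 OK", headers, [body]


def _non_negative_int(params, key, default):
    raw = params.get(key)
    if raw is None:
        return default
    try:
        value = int(raw)
    except ValueError:
        raise _HttpError("400 Bad Request", f"{key} must be an integer")
    if value < 0:
        raise _HttpError("400 Bad Request", f"{key} must be non-negative")
    return value


# ---------------------------------------------------------------------------
# XGMML streaming
# ---------------------------------------------------------------------------

def _node_id(record: InteractionEvidence, side: str) -> str:
    participant = (record.participant_a if side == "a" else record.participant_b)
    if participant.primary_ids:
        ref = participant.primary_ids[0]
        return f"{ref.database}:{ref.identifier}"
    # intra-molecular record: the empty B side reuses A's node (self loop)
    if side == "b" and record.participant_a.primary_ids:
        ref = record.participant_a.primary_ids[0]
        return f"{ref.database}:{ref.identifier}"
    return "unknown"


def stream_xgmml(records: Iterable[InteractionEvidence],
                 label: str = "interaction network",
                 chunk_records: int = 200) -> Iterator[str]:
    """Emit one well-formed XGMML graph as a sequence of text chunks.

    One node per distinct interactor (first primary id), one edge per
    record.  The document is produced incrementally — memory is bounded by
    the distinct-interactor table, never by the record count — so there is
    no cap on exportable result size.
    """
    yield ('<?xml version="1.0" encoding="UTF-8"?>\n'
           f'<graph xmlns="http://www.cs.rpi.edu/XGMML" directed="0" '
           f'label={quoteattr(label)}>\n')
    seen: Dict[str, int] = {}
    buffer: List[str] = []
    edge_number = 0
    for record in records:
        for side in ("a", "b"):
            name = _node_id(record, side)
            if name not in seen:
                seen[name] = len(seen) + 1
                buffer.append(
                    f'  <node id="{seen[name]}" label={quoteattr(name)}/>\n')
        source, target = seen[_node_id(record, "a")], seen[_node_id(record, "b")]
        edge_number += 1
        interaction_label = (record.interaction_ids[0].identifier
                             if record.interaction_ids else f"edge{edge_number}")
        buffer.append(
            f'  <edge id="e{edge_number}" source="{source}" target="{target}" '
            f'label={quoteattr(interaction_label)}/>\n')
        if len(buffer) >= chunk_records:
            yield "".join(buffer)
            buffer = []
    if buffer:
        yield "".join(buffer)
    yield "</graph>\n"


# ---------------------------------------------------------------------------
# Serving
# ---------------------------------------------------------------------------

class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format, *args):  # noqa: A002 - WSGI signature
        pass


def serve(app, host: str = "127.0.0.1", port: int = 0) -> WSGIServer:
    """Create (but do not start) a WSGI server for *app*."""
    return make_server(host, port, app, handler_class=_QuietHandler)


def start_background_server(app, host: str = "127.0.0.1", port: int = 0
                            ) -> Tuple[WSGIServer, threading.Thread, str]:
    """Serve *app* on a daemon thread; returns (server, thread, base_url)."""
    server = serve(app, host, port)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    base_url = f"http://{host}:{server.server_address[1]}"
    return server, thread, base_url
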