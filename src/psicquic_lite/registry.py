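"""Service registry: which interaction providers exist, where, and how big.

A registry is the directory clients consult before federated querying: one
entry per provider with its endpoint URLs, an active flag, the interaction
count, an access-restriction flag, free-text tags and the software version.
The registry here is file-configured (JSON) and served over HTTP with the
conventional query interface::

    GET /registry?action={STATUS|ACTIVE|INACTIVE}&format={xml|txt}[&name=..][&tag=..]

``txt`` emits one ``name=rest_url`` line per entry; ``xml`` emits the
document produced by :func:`to_xml` (and parsed back by
:func:`parse_registry_xml`).  :func:`refresh_counts` polls each service's
``count`` endpoint for the match-all query and marks unreachable services
inactive.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

__all__ = [
    "ServiceEntry", "RegistryError", "registry_query", "to_xml", "to_txt",
    "parse_registry_xml", "parse_registry_txt", "load_registry",
    "save_registry", "refresh_counts", "RegistryApp",
]

ACTIONS = ("STATUS", "ACTIVE", "INACTIVE")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class ServiceEntry:
    """One provider row of the registry."""

    name: str
    rest_url: str
    soap_url: str = ""
    active: bool = True
    interaction_count: int = 0
    restricted: bool = False
    tags: tuple = ()
    version: str = ""

    def __post_init__(self):
        if not self.name:
            raise RegistryError("service name must be non-empty")
        if self.active and not self.rest_url:
            raise RegistryError(
                f"active service {self.name!r} must have a REST URL")
        if self.interaction_count < 0:
            raise RegistryError("interaction_count must be non-negative")
        object.__setattr__(self, "tags", tuple(self.tags))


def _check_unique(entries: Sequence[ServiceEntry]) -> None:
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise RegistryError("service names must be unique within a registry")


def registry_query(entries: Sequence[ServiceEntry], action: str = "STATUS",
                   fmt: str = "xml", name_filter: Optional[str] = None,
                   tag_filter: Optional[str] = None) -> str:
    """Filter entries by action/name/tag and serialize the result."""
    if action not in ACTIONS:
        raise RegistryError(
            f"unknown action {action!r}; expected one of {', '.join(ACTIONS)}")
    _check_unique(entries)
    selected = list(entries)
    if action == "ACTIVE":
        selected = [e for e in selected if e.active]
    elif action == "INACTIVE":
        selected = [e for e in selected if not e.active]
    if name_filter:
        selected = [e for e in selected if e.name.lower() == name_filter.lower()]
    if tag_filter:
        selected = [e for e in selected
                    if tag_filter.lower() in (t.lower() for t in e.tags)]
    if fmt == "xml":
        return to_xml(selected)
    if fmt == "txt":
        return to_txt(selected)
    raise RegistryError(f"unknown format {fmt!r}; expected xml or txt")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def to_xml(entries: Sequence[ServiceEntry]) -> str:
    root = ET.Element("registry")
    for entry in entries:
        service = ET.SubElement(root, "service")
        ET.SubElement(service, "name").text = entry.name
        ET.SubElement(service, "restUrl").text = entry.rest_url
        ET.SubElement(service, "soapUrl").text = entry.soap_url
        ET.SubElement(service, "active").text = "true" if entry.active else "false"
        ET.SubElement(service, "count").text = str(entry.interaction_count)
        ET.SubElement(service, "restricted").text = (
            "true" if entry.restricted else "false")
        ET.SubElement(service, "version").text = entry.version
        tags = ET.SubElement(service, "tags")
        for tag in entry.tags:
            ET.SubElement(tags, "tag").text = tag
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode") + "\n")


def to_txt(entries: Sequence[ServiceEntry]) -> str:
    return "".join(f"{entry.name}={entry.rest_url}\n" for entry in entries)


def parse_registry_xml(document: str) -> List[ServiceEntry]:
    root = ET.fromstring(document)
    entries = []
    for service in root.findall("service"):
        entries.append(ServiceEntry(
            name=service.findtext("name") or "",
            rest_url=service.findtext("restUrl") or "",
            soap_url=service.findtext("soapUrl") or "",
            active=(service.findtext("active") or "false") == "true",
            interaction_count=int(service.findtext("count") or 0),
            restricted=(service.findtext("restricted") or "false") == "true",
            version=service.findtext("version") or "",
            tags=tuple(tag.text or "" for tag in service.findall("tags/tag")),
        ))
    return entries


def parse_registry_txt(document: str) -> List[ServiceEntry]:
    """Parse the name=url listing; fields absent from txt take defaults."""
    entries = []
    for line in document.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise RegistryError(f"malformed registry line: {line!r}")
        name, rest_url = line.split("=", 1)
        entries.append(ServiceEntry(name=name, rest_url=rest_url))
    return entries


# ---------------------------------------------------------------------------
# Configuration file (JSON)
# ---------------------------------------------------------------------------

def load_registry(path) -> List[ServiceEntry]:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    entries = [ServiceEntry(
        name=item["name"],
        rest_url=item.get("rest_url", ""),
        soap_url=item.get("soap_url", ""),
        active=item.get("active", True),
        interaction_count=item.get("interaction_count", 0),
        restricted=item.get("restricted", False),
        tags=tuple(item.get("tags", [])),
        version=item.get("version", ""),
    ) for item in payload["services"]]
    _check_unique(entries)
    return entries


def save_registry(entries: Sequence[ServiceEntry], path) -> None:
    payload = {"services": [{
        "name": e.name, "rest_url": e.rest_url, "soap_url": e.soap_url,
        "active": e.active, "interaction_count": e.interaction_count,
        "restricted": e.restricted, "tags": list(e.tags), "version": e.version,
    } for e in entries]}
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)


# ---------------------------------------------------------------------------
# Count refresh
# ---------------------------------------------------------------------------

def _default_fetch(url: str, timeout: float) -> str:
    with urllib.request.urlopen(url, timeout=timeout) as response:
        return response.read().decode("utf-8")


def count_url(rest_url: str) -> str:
    base = rest_url if rest_url.endswith("/") else rest_url + "/"
    return base + "query/" + urllib.parse.quote("*") + "?format=count"


def refresh_counts(entries: Sequence[ServiceEntry], *,
                   fetch: Optional[Callable[[str], str]] = None,
                   timeout: float = 10.0) -> List[ServiceEntry]:
    """Update interaction counts from each service's count endpoint.

    A service that cannot be reached, or answers garbage, is marked
    inactive; the call itself never raises for network failures.
    """
    refreshed = []
    for entry in entries:
        if not entry.rest_url:
            refreshed.append(replace(entry, active=False))
            continue
        try:
            if fetch is not None:
                body = fetch(count_url(entry.rest_url))
            else:
                body = _default_fetch(count_url(entry.rest_url), timeout)
            count = int(body.strip())
            refreshed.append(replace(entry, active=True,
                                     interaction_count=count))
        except Exception:
            refreshed.append(replace(entry, active=False))
    return refreshed


# ---------------------------------------------------------------------------
# WSGI application
# ---------------------------------------------------------------------------

class RegistryApp:
    """WSGI application serving ``/registry?action=...&format=...``."""

    def __init__(self, entries: Sequence[ServiceEntry]):
        _check_unique(entries)
        self.entries = list(entries)

    def __call__(self, environ, start_response):
        path = environ.get("PATH_INFO", "")
        params = {k: v[-1] for k, v in
                  urllib.parse.parse_qs(environ.get("QUERY_STRING", "")).items()}
        if path.rstrip("/") not in ("/registry", ""):
            return self._respond(start_response, "404 Not Found",
                                 f"no such path: {path}")
        action = params.get("action", "STATUS").upper()
        fmt = params.get("format", "xml")
        try:
            document = registry_query(
                self.entries, action=action, fmt=fmt,
                name_filter=params.get("name"), tag_filter=params.get("tag"))
        except RegistryError as exc:
            return self._respond(start_response, "400 Bad Request", str(exc))
        content_type = ("application/xml" if fmt == "xml" else "text/plain")
        return self._respond(start_response, "200 OK", document,
                             content_type=content_type)

    @staticmethod
    def _respond(start_response, status, text,
                 content_type="text/plain"):
        body = text.encode("utf-8")
        start_response(status, [
            ("Content-Type", f"{content_type}; charset=utf-8"),
            ("Content-Length", str(len(body)))])
        return [body]
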