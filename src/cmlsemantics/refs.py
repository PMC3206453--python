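"""QName-style references and their URI form.

Reference attributes (``dictRef``, ``units``, ``unitType``, ``convention``,
``dataType``) hold prefixed names.  A prefix is resolved first against the
``xmlns`` bindings in scope at the referencing element, then against the
preferred-prefix hints of a local :class:`Catalog`; the namespace URI and the
local part concatenate directly (dictionary namespaces end in ``/``), so each
entry id combined with its dictionary URI yields a globally unique
identifier.  All resolution is offline: URIs are identifiers, dereferenced
only through the catalog's namespace → file map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import (
    CatalogError,
    MalformedReferenceError,
    UnboundPrefixError,
    UnresolvableURIError,
)
from .model import CMLNode, is_ncname, walk

#: Attributes treated as QName references, in reporting order.
REF_ATTRIBUTES = ("convention", "dictRef", "dataType", "units", "unitType")

CONVENTION_NS = "http://www.xml-cml.org/convention/"

#: Preferred prefixes for well-known namespaces (used when a document does
#: not bind the prefix itself).
DEFAULT_PREFIX_HINTS = {
    "convention": CONVENTION_NS,
    "cml": "http://www.xml-cml.org/dictionary/cml/",
    "dummy": "http://www.xml-cml.org/dictionary/dummy/",
    "compchem": "http://www.xml-cml.org/dictionary/compchem/",
    "unit": "http://www.xml-cml.org/unit/nonSi/",
    "si": "http://www.xml-cml.org/unit/si/",
    "unitType": "http://www.xml-cml.org/unit/unitType/",
    "xsd": "http://www.w3.org/2001/XMLSchema",
}


@dataclass(frozen=True)
class QRef:
    """A prefixed reference: ``prefix:local``, both parts non-empty NCNames."""

    prefix: str
    local: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"


def parse_qref(value) -> QRef:
    """Split ``prefix:local``; anything else raises
    :class:`MalformedReferenceError`."""
    if isinstance(value, QRef):
        return value
    if not isinstance(value, str) or value.count(":") != 1:
        raise MalformedReferenceError(value)
    prefix, local = value.split(":")
    if not prefix or not local or not is_ncname(prefix) or not is_ncname(local):
        raise MalformedReferenceError(value)
    return QRef(prefix, local)


def qref_to_uri(ref: QRef, bindings: Mapping[str, str]) -> str:
    """Concatenate the prefix's namespace URI with the local part (no
    separator inserted: namespace URIs conventionally end in ``/``)."""
    try:
        namespace = bindings[ref.prefix]
    except KeyError:
        raise UnboundPrefixError(ref.prefix, in_scope=bindings.keys()) from None
    return namespace + ref.local


@dataclass
class Catalog:
    """Offline resolution context.

    ``bindings`` maps namespace URIs to local files (dictionaries, unit
    dictionaries); ``prefix_hints`` maps preferred prefixes to namespace URIs
    for documents that do not declare the prefix themselves.
    """

    bindings: dict[str, Path] = field(default_factory=dict)
    prefix_hints: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for uri, path in self.bindings.items():
            if not Path(path).exists():
                raise CatalogError(f"catalog maps {uri} to missing file {path}")

    def namespaces(self) -> set[str]:
        return set(self.bindings) | set(self.prefix_hints.values())

    def preferred_prefix(self, namespace: str) -> str | None:
        for prefix in sorted(self.prefix_hints):
            if self.prefix_hints[prefix] == namespace:
                return prefix
        return None


def default_catalog() -> Catalog:
    """Catalog preloaded with the well-known prefixes and the dictionary
    files shipped with the package."""
    from importlib.resources import files

    data = files("cmlsemantics") / "data"
    bindings = {
        "http://www.xml-cml.org/dictionary/dummy/": Path(str(data / "dummy_dictionary.xml")),
        "http://www.xml-cml.org/unit/si/": Path(str(data / "si_units.xml")),
        "http://www.xml-cml.org/unit/nonSi/": Path(str(data / "nonsi_units.xml")),
        "http://www.xml-cml.org/unit/unitType/": Path(str(data / "unittype_dictionary.xml")),
    }
    return Catalog(bindings=bindings, prefix_hints=dict(DEFAULT_PREFIX_HINTS))


def load_catalog(path) -> Catalog:
    """Read a catalog file.

    Line format (whitespace separated, ``#`` comments):

    - ``prefix <prefix> <namespace-uri>``
    - ``map <namespace-uri> <relative-or-absolute-path>``

    Relative paths are resolved against the catalog file's directory.
    """
    path = Path(path)
    bindings: dict[str, Path] = {}
    hints: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3 or fields[0] not in ("prefix", "map"):
            raise CatalogError(f"{path}:{lineno}: cannot parse {raw!r}")
        if fields[0] == "prefix":
            hints[fields[1]] = fields[2]
        else:
            target = Path(fields[2])
            if not target.is_absolute():
                target = path.parent / target
            bindings[fields[1]] = target
    return Catalog(bindings=bindings, prefix_hints=hints)


def uri_to_qref(uri: str, catalog: Catalog) -> QRef:
    """Invert :func:`qref_to_uri`: strip the longest catalogued namespace and
    take the preferred prefix from the catalog's hints."""
    matches = [ns for ns in catalog.namespaces() if uri.startswith(ns) and len(uri) > len(ns)]
    for namespace in sorted(matches, key=len, reverse=True):
        local = uri[len(namespace):]
        prefix = catalog.preferred_prefix(namespace)
        if prefix is not None and is_ncname(local):
            return QRef(prefix, local)
    raise UnresolvableURIError(f"no catalogued namespace matches {uri!r}")


def resolve_qref(ref: QRef, bindings: Mapping[str, str],
                 catalog: Catalog | None = None) -> str:
    """Resolve a QRef to a URI: document ``xmlns`` bindings first, then the
    catalog's prefix hints."""
    merged = dict(catalog.prefix_hints) if catalog is not None else {}
    merged.update({p: u for p, u in bindings.items() if p})
    return qref_to_uri(ref, merged)


@dataclass(frozen=True)
class RefOccurrence:
    """One reference attribute found in a document."""

    path: str
    attribute: str
    raw: str
    qref: QRef | None  # None when the raw value is not a QName
    uri: str | None    # None when the prefix cannot be resolved

    @property
    def resolved(self) -> bool:
        return self.uri is not None


def collect_refs(doc: CMLNode, catalog: Catalog | None = None) -> list[RefOccurrence]:
    """Walk the tree and resolve every reference attribute in document order.

    Malformed or unresolvable references are included, flagged unresolved,
    rather than raising: harvesting needs to see them.
    """
    if catalog is None:
        catalog = default_catalog()
    occurrences: list[RefOccurrence] = []
    for path, node, _ in walk(doc):
        for attr in REF_ATTRIBUTES:
            if attr not in node.attributes:
                continue
            raw = node.attributes[attr]
            qref = uri = None
            try:
                qref = parse_qref(raw)
                uri = resolve_qref(qref, node.in_scope_bindings, catalog)
            except (MalformedReferenceError, UnboundPrefixError):
                pass
            occurrences.append(RefOccurrence(path, attr, raw, qref, uri))
    return occurrences
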