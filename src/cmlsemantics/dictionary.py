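"""Dictionaries: loading, lookup, data checking and scaffolding.

A dictionary gives semantics to abstract CML data carriers: each entry pairs
an id (unique within the dictionary, globally unique once combined with the
dictionary's namespace URI) with a human term, a mandatory one-sentence
definition, optional discursive description, and machine-facing constraints
(dataType, unitType, default units, enumerations, syntactic patterns).

Lookup honours an explicit dictionary hierarchy: a code-specific dictionary
may declare a parent (e.g. the common computational-chemistry dictionary)
which is searched when the id is absent locally.  There must be an entry for
every dictRef; a miss is an error under strict checking and a warning during
folksonomy-stage harvesting.

``harvest_terms`` and ``build_stub_dictionary`` support the corpus-driven
workflow for growing new dictionaries: tally the dictRefs observed in a
document collection, then emit a minimal, rule-conformant stub dictionary
whose entries await human curation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .conventions import (
    DICTIONARY_CONVENTION,
    ERROR,
    INFO,
    ValidationIssue,
    validate,
)
from .errors import (
    DictionaryLoadError,
    MissingEntryError,
    UnknownDictionaryError,
)
from .model import CML_NS, CMLNode, DataItem, is_ncname, read_cml, write_cml
from .refs import (
    CONVENTION_NS,
    Catalog,
    QRef,
    collect_refs,
    default_catalog,
    parse_qref,
    resolve_qref,
)

XSD_NS = "http://www.w3.org/2001/XMLSchema"

_INTEGER_RE = re.compile(r"^[+-]?\d+$")


@dataclass
class Entry:
    """One dictionary entry."""

    id: str
    term: str
    definition: str
    description: CMLNode | None = None
    data_type: str | None = None
    unit_type: str | None = None
    default_units: str | None = None
    enumeration: list[str] | None = None
    pattern: str | None = None
    node: CMLNode | None = None


@dataclass
class DictionaryDoc:
    """An indexed dictionary; ``parent`` links the lookup hierarchy."""

    namespace_uri: str
    prefix: str
    title: str
    entries: dict[str, Entry] = field(default_factory=dict)
    parent: "DictionaryDoc | None" = None
    node: CMLNode | None = None

    def to_cml(self) -> CMLNode:
        if self.node is None:
            raise DictionaryLoadError("dictionary has no source document", None)
        return self.node


def _parse_entry(node: CMLNode) -> Entry:
    definition_nodes = node.child_elements("definition")
    definition = " ".join(definition_nodes[0].all_text().split()) if definition_nodes else ""
    descriptions = node.child_elements("description")
    enumeration = None
    enum_nodes = node.child_elements("enumeration")
    if enum_nodes:
        enumeration = [v.text_content.strip()
                       for v in enum_nodes[0].child_elements("value")]
    pattern_nodes = node.child_elements("pattern")
    return Entry(
        id=node.get("id", ""),
        term=node.get("term", ""),
        definition=definition,
        description=descriptions[0] if descriptions else None,
        data_type=node.get("dataType"),
        unit_type=node.get("unitType"),
        default_units=node.get("units"),
        enumeration=enumeration,
        pattern=pattern_nodes[0].text_content.strip() if pattern_nodes else None,
        node=node,
    )


def load_dictionary(source, catalog: Catalog | None = None) -> DictionaryDoc:
    """Parse and index a dictionary document.

    The dictionary convention's rules run first; any error refuses the load
    (:class:`DictionaryLoadError` with the report attached).
    """
    doc = source if isinstance(source, CMLNode) else read_cml(source)
    report = validate(doc, catalog=catalog, convention=DICTIONARY_CONVENTION)
    if not report.conformant:
        raise DictionaryLoadError(
            f"dictionary failed validation ({len(report.errors)} error(s))", report)
    entries = {}
    for entry_node in doc.child_elements("entry"):
        entry = _parse_entry(entry_node)
        entries[entry.id] = entry
    return DictionaryDoc(
        namespace_uri=doc.get("namespace", ""),
        prefix=doc.get("dictionaryPrefix", ""),
        title=doc.get("title", ""),
        entries=entries,
        node=doc,
    )


class DictionaryRegistry:
    """Dictionaries indexed by namespace URI, with hierarchy-aware lookup."""

    def __init__(self, catalog: Catalog | None = None):
        self.catalog = catalog if catalog is not None else default_catalog()
        self.dictionaries: dict[str, DictionaryDoc] = {}

    def add(self, dictionary: DictionaryDoc,
            parent_namespace: str | None = None) -> DictionaryDoc:
        self.dictionaries[dictionary.namespace_uri] = dictionary
        if parent_namespace is not None:
            dictionary.parent = self.dictionaries[parent_namespace]
        return dictionary

    def load(self, source, parent_namespace: str | None = None) -> DictionaryDoc:
        return self.add(load_dictionary(source, self.catalog), parent_namespace)

    def _split(self, ref, bindings) -> tuple[str, str]:
        if isinstance(ref, (QRef, str)) and not (isinstance(ref, str) and "://" in ref):
            uri = resolve_qref(parse_qref(ref), bindings or {}, self.catalog)
        else:
            uri = str(ref)
        for namespace in sorted(self.dictionaries, key=len, reverse=True):
            if uri.startswith(namespace) and len(uri) > len(namespace):
                return namespace, uri[len(namespace):]
        raise UnknownDictionaryError(f"no dictionary registered for {uri}")

    def lookup(self, ref, bindings=None) -> Entry:
        """Resolve a dictRef (QRef text, :class:`QRef` or URI) to its entry,
        searching the parent chain of the addressed dictionary."""
        namespace, local = self._split(ref, bindings)
        dictionary = self.dictionaries[namespace]
        chain = []
        while dictionary is not None:
            chain.append(dictionary.prefix or dictionary.namespace_uri)
            if local in dictionary.entries:
                return dictionary.entries[local]
            dictionary = dictionary.parent
        raise MissingEntryError(
            f"no entry {local!r} in dictionary chain: {' -> '.join(chain)}")


def default_dictionary_registry(catalog: Catalog | None = None) -> DictionaryRegistry:
    """Registry preloaded with every dictionary the catalog maps to a file."""
    registry = DictionaryRegistry(catalog)
    for path in registry.catalog.bindings.values():
        doc = read_cml(path)
        if doc.name == "dictionary":
            # unit dictionaries index as plain dictionaries too: their
            # entries resolve dictRef-style lookups
            try:
                registry.add(load_dictionary(doc, registry.catalog))
            except DictionaryLoadError:
                continue
    return registry


# ---------------------------------------------------------------------------
# run-time data checking


def _value_matches_type(value: str, data_type: str | None) -> bool:
    local = (data_type or "string").rsplit(":", 1)[-1]
    if local in ("double", "float", "decimal"):
        try:
            float(value)
            return True
        except ValueError:
            return False
    if local in ("integer", "int", "long"):
        return bool(_INTEGER_RE.match(value))
    return True  # xsd:string and unknown types accept anything


def _ref_uri(ref_text: str | None, bindings, catalog: Catalog) -> str | None:
    if ref_text is None:
        return None
    try:
        return resolve_qref(parse_qref(ref_text), bindings or {}, catalog)
    except Exception:
        return None


def check_data(item: DataItem, entry: Entry, units_registry=None,
               catalog: Catalog | None = None, path: str = "") -> list[ValidationIssue]:
    """Check a data item against its dictionary entry.

    DAT-001 value fails the entry's dataType; DAT-002 value outside the
    enumeration; DAT-003 the item's units imply a unitType conflicting with
    the entry's; DAT-004 (info) the item has no units and the entry's
    default applies.
    """
    if catalog is None:
        catalog = default_catalog()
    bindings = item.node.in_scope_bindings
    issues: list[ValidationIssue] = []
    for value in item.values:
        if not _value_matches_type(value, entry.data_type):
            issues.append(ValidationIssue(
                ERROR, "DAT-001", path,
                f"value {value!r} is not a valid {entry.data_type}"))
        if entry.enumeration is not None and value not in entry.enumeration:
            issues.append(ValidationIssue(
                ERROR, "DAT-002", path,
                f"value {value!r} not in enumeration {entry.enumeration}"))

    entry_type_uri = _ref_uri(entry.unit_type,
                              entry.node.in_scope_bindings if entry.node else None,
                              catalog)
    if entry_type_uri is not None:
        item_type_uris: set[str] = set()
        if item.unit_type is not None:
            uri = _ref_uri(item.unit_type, bindings, catalog)
            if uri:
                item_type_uris.add(uri)
        elif item.units is not None and units_registry is not None:
            try:
                for unit in units_registry.resolve_unit(item.units, bindings):
                    uri = _ref_uri(unit.unit_type, bindings, catalog)
                    if uri:
                        item_type_uris.add(uri)
            except Exception:
                pass
        if item_type_uris and entry_type_uri not in item_type_uris:
            issues.append(ValidationIssue(
                ERROR, "DAT-003", path,
                f"item unitType {sorted(item_type_uris)} conflicts with "
                f"entry unitType {entry_type_uri}"))

    if item.units is None and entry.default_units is not None:
        issues.append(ValidationIssue(
            INFO, "DAT-004", path,
            f"no units given; entry default applied: {entry.default_units}"))
    return issues


def effective_units(item: DataItem, entry: Entry | None = None) -> str | None:
    """The item's units, falling back to the entry's declared default."""
    if item.units is not None:
        return item.units
    return entry.default_units if entry is not None else None


# ---------------------------------------------------------------------------
# harvesting and scaffolding


@dataclass
class HarvestRecord:
    qref: str
    count: int
    paths: list[str]
    resolved: bool


def harvest_terms(corpus, registry: DictionaryRegistry | None = None,
                  catalog: Catalog | None = None) -> dict[str, HarvestRecord]:
    """Tally every dictRef occurrence over a corpus of documents.

    Returns a mapping ordered by descending count then lexicographic
    reference text; each record keeps up to 3 example paths (prefixed with
    the 0-based document index) and whether the reference resolves to an
    entry in the registry.
    """
    if catalog is None:
        catalog = registry.catalog if registry is not None else default_catalog()
    records: dict[str, HarvestRecord] = {}
    for index, doc in enumerate(corpus):
        for occ in collect_refs(doc, catalog):
            if occ.attribute != "dictRef":
                continue
            key = str(occ.qref) if occ.qref is not None else occ.raw
            record = records.get(key)
            if record is None:
                resolved = False
                if registry is not None and occ.uri is not None:
                    try:
                        registry.lookup(occ.uri)
                        resolved = True
                    except (UnknownDictionaryError, MissingEntryError):
                        resolved = False
                record = records[key] = HarvestRecord(key, 0, [], resolved)
            record.count += 1
            if len(record.paths) < 3:
                record.paths.append(f"doc[{index}]{occ.path}")
    return dict(sorted(records.items(), key=lambda kv: (-kv[1].count, kv[0])))


def harvest_report_tsv(records: dict[str, HarvestRecord]) -> str:
    """TSV rendering: qref, count, resolved, example_path."""
    lines = ["qref\tcount\tresolved\texample_path"]
    for record in records.values():
        example = record.paths[0] if record.paths else ""
        lines.append(f"{record.qref}\t{record.count}\t"
                     f"{'yes' if record.resolved else 'no'}\t{example}")
    return "\n".join(lines) + "\n"


STUB_DEFINITION = "TODO: definition pending communal curation."


def _element(name: str, attributes: dict[str, str], bindings: dict[str, str],
             text: str = "", children: list[CMLNode] | None = None) -> CMLNode:
    return CMLNode(name=name, namespace_uri=CML_NS, attributes=attributes,
                   text_content=text, children=children or [],
                   in_scope_bindings=bindings)


def build_stub_dictionary(terms, namespace_uri: str, prefix: str,
                          observed=None) -> DictionaryDoc:
    """Scaffold a minimal dictionary for unresolved harvested terms.

    *terms* may be local names, ``prefix:local`` texts or :class:`QRef`s
    (only the local part is used).  *observed*, when given, maps a local
    name to ``(kind, values)`` — the data structure seen in the corpus and
    sample value texts; all-numeric samples infer ``xsd:double``, anything
    else ``xsd:string`` (deliberately crude: real typing is a curation
    decision).  Locals that are not valid NCNames are skipped with a
    warning.  The emitted document always passes the dictionary convention.
    """
    bindings = {"": CML_NS, "convention": CONVENTION_NS, "xsd": XSD_NS}
    observed = observed or {}
    entry_nodes: list[CMLNode] = []
    seen: set[str] = set()
    for term in terms:
        local = term.local if isinstance(term, QRef) else str(term).rsplit(":", 1)[-1]
        if not is_ncname(local):
            warnings.warn(f"skipping term with invalid NCName local: {local!r}")
            continue
        if local in seen:
            continue
        seen.add(local)
        attributes = {"id": local, "term": local}
        if local in observed:
            kind, values = observed[local]
            attributes["dataStructure"] = kind
            numeric = bool(values) and all(
                _value_matches_type(v, "xsd:double") for v in values)
            attributes["dataType"] = "xsd:double" if numeric else "xsd:string"
        definition = _element("definition", {}, bindings, text=STUB_DEFINITION)
        entry_nodes.append(_element("entry", attributes, bindings,
                                    children=[definition]))
    root = _element(
        "dictionary",
        {
            "convention": "convention:dictionary",
            "title": f"{prefix} stub dictionary (awaiting curation)",
            "namespace": namespace_uri,
            "dictionaryPrefix": prefix,
        },
        bindings,
        children=entry_nodes,
    )
    return load_dictionary(root)


__all__ = [
    "Entry", "DictionaryDoc", "DictionaryRegistry", "HarvestRecord",
    "load_dictionary", "default_dictionary_registry", "check_data",
    "effective_units", "harvest_terms", "harvest_report_tsv",
    "build_stub_dictionary", "STUB_DEFINITION",
]
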