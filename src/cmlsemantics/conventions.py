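"""Convention detection and rule-based validation.

A ``convention`` attribute announces that its element and all descendants
follow the constraints a sub-community has agreed to, until overridden by a
nested ``convention`` attribute.  Validation walks each such scope with the
rule set registered for the convention's URI and accumulates
:class:`ValidationIssue` records; elements outside every scope are
transparently ignored.  Unknown conventions are warnings, not errors — any
group may mint its own, and a validator cannot enumerate them all.

The built-in rule sets cover the five core conventions (``dictionary``,
``molecular``, ``compchem``, ``unit-dictionary``, ``unitType-dictionary``)
at the level of their published structural constraints, e.g. for molecular
documents: a non-empty atomArray, atom-id uniqueness within the eldest
containing molecule, and bond endpoints resolving inside that molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .errors import MalformedReferenceError, UnboundPrefixError
from .model import CMLNode, is_ncname, walk
from .refs import CONVENTION_NS, Catalog, default_catalog, parse_qref, resolve_qref

ERROR = "error"
WARNING = "warning"
INFO = "info"

MOLECULAR_CONVENTION = CONVENTION_NS + "molecular"
DICTIONARY_CONVENTION = CONVENTION_NS + "dictionary"
COMPCHEM_CONVENTION = CONVENTION_NS + "compchem"
UNIT_DICTIONARY_CONVENTION = CONVENTION_NS + "unit-dictionary"
UNITTYPE_DICTIONARY_CONVENTION = CONVENTION_NS + "unitType-dictionary"


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    rule_code: str
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper():7s} {self.rule_code:8s} {self.path}: {self.message}"


@dataclass
class ValidationReport:
    """Ordered list of issues; conformant iff no error-severity issue."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == ERROR]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == WARNING]

    @property
    def conformant(self) -> bool:
        return not self.errors

    def rule_codes(self) -> set[str]:
        return {i.rule_code for i in self.issues}

    def to_json(self) -> str:
        return json.dumps(
            {
                "conformant": self.conformant,
                "issues": [vars(i) for i in self.issues],
            },
            indent=2,
        )

    def __str__(self) -> str:
        if not self.issues:
            return "no issues"
        return "\n".join(str(i) for i in self.issues)


class Scope:
    """One convention scope: an element plus descendants, minus any nested
    subtree that declares its own convention."""

    def __init__(self, root: CMLNode, root_path: str, catalog: Catalog):
        self.root = root
        self.root_path = root_path
        self.catalog = catalog

    def iter(self) -> Iterator[tuple[str, CMLNode, tuple[CMLNode, ...]]]:
        """Yield (path, node, in-scope ancestors) in document order."""

        def _walk(node, path, ancestors):
            yield path, node, ancestors
            counts: dict[str, int] = {}
            for child in node.children:
                counts[child.name] = counts.get(child.name, 0) + 1
                if "convention" in child.attributes:
                    continue  # nested convention overrides for its subtree
                child_path = f"{path}/{child.name}[{counts[child.name]}]"
                yield from _walk(child, child_path, ancestors + (node,))

        yield from _walk(self.root, self.root_path, ())

    def resolvable(self, value: str, node: CMLNode) -> bool:
        try:
            resolve_qref(parse_qref(value), node.in_scope_bindings, self.catalog)
            return True
        except (MalformedReferenceError, UnboundPrefixError):
            return False


RuleSet = Callable[[Scope], list[ValidationIssue]]


@dataclass
class ConventionSpec:
    name: str
    namespace_uri: str
    rules: list[RuleSet]


# ---------------------------------------------------------------------------
# molecular convention


def molecular_rules(scope: Scope) -> list[ValidationIssue]:
    """Constraints of the molecular convention.

    MOL-001 empty atomArray; MOL-002 duplicate atom id within the eldest
    containing molecule; MOL-003 bond without atomRefs2; MOL-004 bond
    endpoint not an atom id of the eldest containing molecule; MOL-005
    atomRefs2 not exactly two tokens.
    """
    entries = list(scope.iter())
    issues: list[ValidationIssue] = []

    for path, node, _ in entries:
        if node.name == "atomArray" and not node.child_elements("atom"):
            issues.append(ValidationIssue(
                ERROR, "MOL-001", path, "atomArray must have at least one atom child"))

    # eldest molecules: no molecule ancestor within the scope
    eldest = [(p, n) for p, n, anc in entries
              if n.name == "molecule" and not any(a.name == "molecule" for a in anc)]
    for mol_path, mol in eldest:
        atom_ids: set[str] = set()
        for path, node, anc in entries:
            if node.name == "atom" and (node is mol or mol in anc):
                atom_id = node.get("id")
                if atom_id is None:
                    continue
                if atom_id in atom_ids:
                    issues.append(ValidationIssue(
                        ERROR, "MOL-002", path,
                        f"atom id {atom_id!r} duplicated within eldest molecule "
                        f"{mol.get('id')!r}"))
                atom_ids.add(atom_id)
        for path, node, anc in entries:
            if node.name != "bond" or mol not in anc:
                continue
            raw = node.get("atomRefs2")
            if raw is None:
                issues.append(ValidationIssue(
                    ERROR, "MOL-003", path, "bond must have an atomRefs2 attribute"))
                continue
            tokens = raw.split()
            if len(tokens) != 2:
                issues.append(ValidationIssue(
                    ERROR, "MOL-005", path,
                    f"atomRefs2 must contain exactly 2 tokens, found {len(tokens)}"))
            for token in tokens:
                if token not in atom_ids:
                    issues.append(ValidationIssue(
                        ERROR, "MOL-004", path,
                        f"bond endpoint {token!r} matches no atom id within "
                        f"eldest molecule {mol.get('id')!r}"))
    return issues


# ---------------------------------------------------------------------------
# dictionary conventions


def _scope_entries(scope: Scope) -> list[tuple[str, CMLNode]]:
    """Direct entry children of the dictionary root, with paths."""
    return [(path, node) for path, node, anc in scope.iter()
            if node.name == "entry" and anc and anc[-1] is scope.root]


def dictionary_rules(scope: Scope) -> list[ValidationIssue]:
    """Structural constraints of the dictionary convention (DIC-001..005)."""
    issues: list[ValidationIssue] = []
    root = scope.root
    if root.name != "dictionary":
        return [ValidationIssue(ERROR, "DIC-001", scope.root_path,
                                f"expected a dictionary element, found <{root.name}>")]
    for attr in ("namespace", "dictionaryPrefix", "title"):
        if not root.get(attr):
            issues.append(ValidationIssue(
                ERROR, "DIC-001", scope.root_path,
                f"dictionary root must carry a non-empty {attr!r} attribute"))

    seen_ids: set[str] = set()
    for path, entry in _scope_entries(scope):
        entry_id = entry.get("id")
        definitions = [d for d in entry.child_elements("definition")
                       if d.all_text().strip()]
        if not entry_id or not entry.get("term") or not definitions:
            issues.append(ValidationIssue(
                ERROR, "DIC-002", path,
                "entry must have non-empty id, term and a definition child"))
        if entry_id:
            if entry_id in seen_ids:
                issues.append(ValidationIssue(
                    ERROR, "DIC-003", path,
                    f"entry id {entry_id!r} duplicated within dictionary"))
            seen_ids.add(entry_id)
            if not is_ncname(entry_id):
                issues.append(ValidationIssue(
                    ERROR, "DIC-005", path,
                    f"entry id {entry_id!r} is not a valid NCName"))
        for attr in ("dataType", "units", "unitType"):
            value = entry.get(attr)
            if value is not None and not scope.resolvable(value, entry):
                issues.append(ValidationIssue(
                    ERROR, "DIC-004", path,
                    f"{attr}={value!r} is not a QName with a resolvable prefix"))
    return issues


def unit_dictionary_rules(scope: Scope) -> list[ValidationIssue]:
    """Unit-dictionary constraints: every unit names its unitType (UND-001)
    and a conversion factor to the SI-coherent base of its dimension
    (UND-002, encoded as multiplierToSI; see docs/formats.md)."""
    issues: list[ValidationIssue] = []
    for path, entry in _scope_entries(scope):
        unit_type = entry.get("unitType")
        if not unit_type or not scope.resolvable(unit_type, entry):
            issues.append(ValidationIssue(
                ERROR, "UND-001", path,
                "unit entry must reference a unitType"))
        factor = entry.get("multiplierToSI")
        ok = False
        if factor is not None:
            try:
                ok = float(factor) > 0
            except ValueError:
                ok = False
        if not ok:
            issues.append(ValidationIssue(
                ERROR, "UND-002", path,
                "unit entry must provide a positive multiplierToSI conversion factor"))
    return issues


def unittype_dictionary_rules(scope: Scope) -> list[ValidationIssue]:
    """unitType-dictionary constraint: every entry declares its dimension
    exponents (UTD-001; empty string means pure dimensionless)."""
    from .units import DimensionSyntaxError, parse_dimension  # local: avoid cycle

    issues: list[ValidationIssue] = []
    for path, entry in _scope_entries(scope):
        declared = entry.get("dimension")
        if declared is None:
            issues.append(ValidationIssue(
                ERROR, "UTD-001", path,
                "unitType entry must specify a dimension declaration"))
            continue
        try:
            parse_dimension(declared)
        except DimensionSyntaxError as exc:
            issues.append(ValidationIssue(
                ERROR, "UTD-001", path, f"unparseable dimension declaration: {exc}"))
    return issues


# ---------------------------------------------------------------------------
# compchem convention


def compchem_rules(scope: Scope) -> list[ValidationIssue]:
    """Minimal compchem constraints: parameters and properties carry a
    dictRef (CC-001) and hold their value as scalar/array/matrix children
    (CC-002)."""
    issues: list[ValidationIssue] = []
    for path, node, _ in scope.iter():
        if node.name not in ("parameter", "property"):
            continue
        if not node.get("dictRef"):
            issues.append(ValidationIssue(
                ERROR, "CC-001", path, f"{node.name} must carry a dictRef"))
        if not any(c.name in ("scalar", "array", "matrix") for c in node.children):
            issues.append(ValidationIssue(
                ERROR, "CC-002", path,
                f"{node.name} must hold its value as a scalar/array/matrix child"))
    return issues


# ---------------------------------------------------------------------------
# detection and validation


def default_convention_registry() -> list[ConventionSpec]:
    return [
        ConventionSpec("dictionary", DICTIONARY_CONVENTION, [dictionary_rules]),
        ConventionSpec("molecular", MOLECULAR_CONVENTION, [molecular_rules]),
        ConventionSpec("compchem", COMPCHEM_CONVENTION, [compchem_rules]),
        ConventionSpec("unit-dictionary", UNIT_DICTIONARY_CONVENTION,
                       [unit_dictionary_rules]),
        ConventionSpec("unitType-dictionary", UNITTYPE_DICTIONARY_CONVENTION,
                       [unittype_dictionary_rules]),
    ]


@dataclass(frozen=True)
class ConventionHit:
    path: str
    raw: str
    uri: str | None  # None when the convention QRef cannot be resolved

    @property
    def resolved(self) -> bool:
        return self.uri is not None


def detect(doc: CMLNode, catalog: Catalog | None = None) -> list[ConventionHit]:
    """Every element bearing a convention attribute, with its resolved URI;
    each scope covers the element and descendants until a nested override."""
    if catalog is None:
        catalog = default_catalog()
    hits = []
    for path, node, _ in walk(doc):
        raw = node.get("convention")
        if raw is None:
            continue
        try:
            uri = resolve_qref(parse_qref(raw), node.in_scope_bindings, catalog)
        except (MalformedReferenceError, UnboundPrefixError):
            uri = None
        hits.append(ConventionHit(path, raw, uri))
    return hits


def validate(
    doc: CMLNode,
    registry: list[ConventionSpec] | None = None,
    catalog: Catalog | None = None,
    convention: str | None = None,
) -> ValidationReport:
    """Validate *doc* against every detected convention scope.

    ``convention`` (a namespace URI) forces the whole document to be checked
    under that single convention, ignoring declared attributes.  Issues are
    ordered by document position then rule code; the document is conformant
    iff no error-severity issue is present.
    """
    if registry is None:
        registry = default_convention_registry()
    if catalog is None:
        catalog = default_catalog()
    by_uri = {spec.namespace_uri: spec for spec in registry}

    nodes_by_path = {path: node for path, node, _ in walk(doc)}
    order = {path: i for i, path in enumerate(nodes_by_path)}

    issues: list[ValidationIssue] = []
    if convention is not None:
        scoped = [(f"/{doc.name}", doc, convention)]
    else:
        scoped = []
        for hit in detect(doc, catalog):
            if hit.uri is None:
                issues.append(ValidationIssue(
                    ERROR, "CNV-001", hit.path,
                    f"convention reference {hit.raw!r} cannot be resolved"))
            else:
                scoped.append((hit.path, nodes_by_path[hit.path], hit.uri))

    for path, node, uri in scoped:
        spec = by_uri.get(uri)
        if spec is None:
            issues.append(ValidationIssue(
                WARNING, "CNV-002", path,
                f"unknown convention {uri}: no registered rule set"))
            continue
        scope = Scope(node, path, catalog)
        for rule_set in spec.rules:
            issues.extend(rule_set(scope))

    issues.sort(key=lambda i: (order.get(i.path, len(order)), i.rule_code))
    return ValidationReport(issues)


def conformant(doc: CMLNode, **kwargs) -> bool:
    return validate(doc, **kwargs).conformant
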