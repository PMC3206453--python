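"""Reference documents and seeded synthetic generators.

Ships the two complete exemplar documents of the semantic layer — the
"dummy" concept dictionary (molecular/molar mass) and a polymer fragment
with role/dictRef tagging — as reviewable files, together with the 21
chemical-synthesis action phrases used to seed a natural-language-derived
dictionary.

The generators produce conformant synthetic documents (molecules over a
random spanning tree, compchem parameter corpora with known term
frequencies) and :func:`mutation_suite` provides one single-fault transform
per validation rule code, so every rule has both a passing and a failing
fixture and rule independence can be checked mechanically.  All randomness
is driven by one explicit integer seed; identical seeds give identical
bytes.
"""

from __future__ import annotations

import random
import shutil
from collections import Counter
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Callable

from .errors import InapplicableMutationError
from .model import CML_NS, CMLNode, find_all, read_cml
from .refs import CONVENTION_NS
from .units import NONSI_NS, UnitDef, UnitsRegistry, default_units_registry

_FIXTURE_FILES = (
    "dummy_dictionary.xml",
    "polymer_fragment.xml",
    "action_phrases.txt",
    "unittype_dictionary.xml",
    "si_units.xml",
    "nonsi_units.xml",
)

XSD_NS = "http://www.w3.org/2001/XMLSchema"


def fixture_path(name: str) -> Path:
    return Path(str(files("cmlsemantics") / "data" / name))


@dataclass
class PaperFixtures:
    dummy_dictionary: CMLNode
    polymer_fragment: CMLNode
    action_phrases: list[str]


def paper_fixtures() -> PaperFixtures:
    """The exemplar documents, freshly parsed, plus the 21 action phrases."""
    phrases = fixture_path("action_phrases.txt").read_text().split()
    return PaperFixtures(
        dummy_dictionary=read_cml(fixture_path("dummy_dictionary.xml")),
        polymer_fragment=read_cml(fixture_path("polymer_fragment.xml")),
        action_phrases=phrases,
    )


def export_fixtures(directory) -> list[Path]:
    """Copy every fixture file into *directory*; returns the new paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name in _FIXTURE_FILES:
        target = directory / name
        shutil.copyfile(fixture_path(name), target)
        out.append(target)
    return out


# ---------------------------------------------------------------------------
# element construction helpers


def _element(name: str, attributes: dict[str, str] | None = None,
             bindings: dict[str, str] | None = None, text: str = "",
             children: list[CMLNode] | None = None) -> CMLNode:
    return CMLNode(name=name, namespace_uri=CML_NS,
                   attributes=attributes or {}, text_content=text,
                   children=children or [],
                   in_scope_bindings=bindings or {"": CML_NS})


_ELEMENTS = ("C", "N", "O", "S", "P", "H")


def generate_molecular(seed: int, n_atoms: int, nested: bool = False) -> CMLNode:
    """A conformant synthetic molecule under the molecular convention.

    Atoms get unique ids and random coordinates; bonds span a random
    spanning tree (n_atoms - 1 bonds).  With ``nested`` a child molecule
    (3 atoms, 2 bonds) is embedded with ids disjoint from the parent's, so
    the eldest-molecule uniqueness rule still holds.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = random.Random(seed)
    bindings = {"": CML_NS, "convention": CONVENTION_NS}

    def make_atoms(prefix: str, count: int) -> list[CMLNode]:
        atoms = []
        for i in range(1, count + 1):
            atoms.append(_element("atom", {
                "id": f"{prefix}{i}",
                "elementType": rng.choice(_ELEMENTS),
                "x3": f"{rng.uniform(-10, 10):.4f}",
                "y3": f"{rng.uniform(-10, 10):.4f}",
                "z3": f"{rng.uniform(-10, 10):.4f}",
            }, bindings))
        return atoms

    def make_bonds(prefix: str, count: int) -> list[CMLNode]:
        bonds = []
        for i in range(2, count + 1):
            partner = rng.randrange(1, i)
            bonds.append(_element("bond", {
                "id": f"{prefix}{partner}_{prefix}{i}",
                "atomRefs2": f"{prefix}{partner} {prefix}{i}",
                "order": rng.choice(("1", "2", "S")),
            }, bindings))
        return bonds

    children = [
        _element("atomArray", {}, bindings, children=make_atoms("a", n_atoms)),
    ]
    if n_atoms > 1:
        children.append(
            _element("bondArray", {}, bindings, children=make_bonds("a", n_atoms)))
    if nested:
        inner = _element("molecule", {"id": "m_inner"}, bindings, children=[
            _element("atomArray", {}, bindings, children=make_atoms("n", 3)),
            _element("bondArray", {}, bindings, children=make_bonds("n", 3)),
        ])
        children.append(inner)
    return _element("molecule",
                    {"id": "m1", "convention": "convention:molecular"},
                    bindings, children=children)


def compchem_example() -> CMLNode:
    """A minimal conformant compchem document: parameters and a property,
    each dictRef'd, each holding a scalar."""
    bindings = {"": CML_NS, "convention": CONVENTION_NS,
                "cc": "http://www.xml-cml.org/dictionary/cc/", "xsd": XSD_NS}

    def parameter(ref: str, value: str, data_type: str = "xsd:string") -> CMLNode:
        return _element("parameter", {"dictRef": ref}, bindings, children=[
            _element("scalar", {"dataType": data_type}, bindings, text=value)])

    module = _element("module", {"role": "environment"}, bindings, children=[
        _element("parameterList", {}, bindings, children=[
            parameter("cc:hostname", "node042"),
            parameter("cc:program", "testcode"),
        ]),
        _element("propertyList", {}, bindings, children=[
            _element("property", {"dictRef": "cc:totalEnergy"}, bindings, children=[
                _element("scalar",
                         {"dataType": "xsd:double", "units": "si:kilogram"},
                         bindings, text="-76.4")]),
        ]),
    ])
    return _element("cml", {"convention": "convention:compchem"}, bindings,
                    children=[module])


def units_usage_example() -> CMLNode:
    """A document whose data items all carry resolvable units — the clean
    baseline for units-usage checks."""
    bindings = {"": CML_NS, "unit": NONSI_NS, "xsd": XSD_NS,
                "dummy": "http://www.xml-cml.org/dictionary/dummy/"}
    return _element("cml", {}, bindings, children=[
        _element("property", {"dictRef": "dummy:molecmass"}, bindings, children=[
            _element("scalar", {"dataType": "xsd:double", "units": "unit:dalton"},
                     bindings, text="180.16")]),
        _element("property", {"dictRef": "dummy:molarmass"}, bindings, children=[
            _element("scalar",
                     {"dataType": "xsd:double", "units": "unit:gramPerMole"},
                     bindings, text="180.16")]),
    ])


def units_usage_registry() -> UnitsRegistry:
    """Default units registry plus one deliberately broken registration
    (a unit whose unitType is nowhere declared) to exercise UNI-002."""
    registry = default_units_registry()
    registry.units[NONSI_NS + "legacyFoo"] = [
        UnitDef("legacyFoo", unit_type="unitType:mystery", factor_to_base=1.0)]
    return registry


# ---------------------------------------------------------------------------
# compchem corpus generation


@dataclass
class Corpus:
    """Synthetic harvesting corpus with the generator's own tallies as the
    ground-truth oracle."""

    docs: list[CMLNode]
    expected_counts: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.docs)

    def __len__(self):
        return len(self.docs)


def generate_compchem_corpus(seed: int, n_docs: int, known_terms,
                             unknown_terms=()) -> Corpus:
    """Generate *n_docs* compchem documents for harvesting.

    Every known term appears exactly once per document; each unknown term is
    repeated 0-2 times per document (seeded).  Prefixes used by the terms
    are bound to ``http://www.xml-cml.org/dictionary/<prefix>/`` in each
    document, so references resolve without catalog hints.
    """
    if n_docs < 0:
        raise ValueError("n_docs must be >= 0")
    rng = random.Random(seed)
    known_terms = list(known_terms)
    unknown_terms = list(unknown_terms)
    prefixes = {t.split(":")[0] for t in known_terms + unknown_terms if ":" in t}
    bindings = {"": CML_NS, "convention": CONVENTION_NS, "xsd": XSD_NS}
    for prefix in sorted(prefixes):
        bindings[prefix] = f"http://www.xml-cml.org/dictionary/{prefix}/"

    docs: list[CMLNode] = []
    counts: Counter = Counter()
    for _ in range(n_docs):
        parameters = []
        for term in known_terms:
            parameters.append(_element("parameter", {"dictRef": term}, bindings,
                                       children=[_element("scalar",
                                                          {"dataType": "xsd:string"},
                                                          bindings,
                                                          text=f"v{rng.randrange(1000)}")]))
            counts[term] += 1
        for term in unknown_terms:
            for _ in range(rng.randrange(3)):
                parameters.append(_element("parameter", {"dictRef": term}, bindings,
                                           children=[_element("scalar",
                                                              {"dataType": "xsd:string"},
                                                              bindings,
                                                              text=f"v{rng.randrange(1000)}")]))
                counts[term] += 1
        module = _element("module", {}, bindings, children=[
            _element("parameterList", {}, bindings, children=parameters)])
        docs.append(_element("cml", {"convention": "convention:compchem"},
                             bindings, children=[module]))
    return Corpus(docs=docs, expected_counts=counts)


# ---------------------------------------------------------------------------
# single-fault mutations


@dataclass
class MutationSpec:
    """One targeted fault: applied to a conformant base document it must
    fail exactly ``target_rule`` and nothing else."""

    target_rule: str
    description: str
    base: str  # key understood by base_document()
    transform: Callable[[CMLNode], None]


def mutate(doc: CMLNode, spec: MutationSpec) -> CMLNode:
    """Apply the spec's transform to a deep copy of *doc*."""
    mutant = doc.deep_copy()
    spec.transform(mutant)
    return mutant


def base_document(spec: MutationSpec) -> CMLNode:
    factories = {
        "molecular": lambda: generate_molecular(seed=7, n_atoms=5),
        "dictionary": lambda: paper_fixtures().dummy_dictionary,
        "unit_dictionary": lambda: read_cml(fixture_path("si_units.xml")),
        "unittype_dictionary": lambda: read_cml(fixture_path("unittype_dictionary.xml")),
        "compchem": compchem_example,
        "units_usage": units_usage_example,
    }
    return factories[spec.base]()


def _first(doc: CMLNode, name: str, having: str | None = None) -> CMLNode:
    for node in find_all(doc, name):
        if having is None or having in node.attributes:
            return node
    raise InapplicableMutationError(f"no <{name}> "
                                    f"{'with ' + having if having else ''} to mutate")


def _require_molecule(doc: CMLNode) -> CMLNode:
    return _first(doc, "molecule")


def _mol_empty_atomarray(doc):
    mol = _require_molecule(doc)
    mol.children.append(CMLNode("atomArray", CML_NS,
                                in_scope_bindings=dict(mol.in_scope_bindings)))


def _mol_duplicate_id(doc):
    first_atom = _first(doc, "atom", having="id")
    array = _first(doc, "atomArray")
    clone = CMLNode("atom", CML_NS,
                    attributes={"id": first_atom.attributes["id"],
                                "elementType": "C"},
                    in_scope_bindings=dict(array.in_scope_bindings))
    array.children.append(clone)


def _mol_drop_atomrefs(doc):
    del _first(doc, "bond", having="atomRefs2").attributes["atomRefs2"]


def _mol_ghost_endpoint(doc):
    bond = _first(doc, "bond", having="atomRefs2")
    first_token = bond.attributes["atomRefs2"].split()[0]
    bond.attributes["atomRefs2"] = f"{first_token} ghost_atom"


def _mol_three_tokens(doc):
    ids = [a.attributes["id"] for a in find_all(doc, "atom") if "id" in a.attributes]
    if len(ids) < 3:
        raise InapplicableMutationError("need >= 3 atoms for a 3-token atomRefs2")
    bond = _first(doc, "bond", having="atomRefs2")
    bond.attributes["atomRefs2"] = " ".join(ids[:3])


def _dic_drop_title(doc):
    del doc.attributes["title"]


def _dic_drop_definition(doc):
    entry = _first(doc, "entry")
    entry.children = [c for c in entry.children if c.name != "definition"]


def _dic_duplicate_entry(doc):
    doc.children.append(_first(doc, "entry").deep_copy())


def _dic_bare_units(doc):
    _first(doc, "entry").attributes["units"] = "dalton"


def _dic_bad_ncname(doc):
    _first(doc, "entry").attributes["id"] = "1badid"


def _utd_drop_dimension(doc):
    del _first(doc, "entry", having="dimension").attributes["dimension"]


def _und_drop_unittype(doc):
    del _first(doc, "entry", having="unitType").attributes["unitType"]


def _und_drop_factor(doc):
    del _first(doc, "entry", having="multiplierToSI").attributes["multiplierToSI"]


def _cc_drop_dictref(doc):
    del _first(doc, "parameter", having="dictRef").attributes["dictRef"]


def _cc_drop_scalar(doc):
    parameter = _first(doc, "parameter")
    parameter.children = [c for c in parameter.children
                          if c.name not in ("scalar", "array", "matrix")]


def _uni_unknown_units(doc):
    _first(doc, "scalar", having="units").attributes["units"] = "zzz:unknown"


def _uni_typeless_unit(doc):
    _first(doc, "scalar", having="units").attributes["units"] = "unit:legacyFoo"


def _uni_drop_units(doc):
    del _first(doc, "scalar", having="units").attributes["units"]


def mutation_suite() -> list[MutationSpec]:
    """One single-fault spec per validation rule code."""
    return [
        MutationSpec("MOL-001", "append an empty atomArray", "molecular",
                     _mol_empty_atomarray),
        MutationSpec("MOL-002", "add an atom duplicating an existing id",
                     "molecular", _mol_duplicate_id),
        MutationSpec("MOL-003", "remove atomRefs2 from a bond", "molecular",
                     _mol_drop_atomrefs),
        MutationSpec("MOL-004", "point a bond endpoint at a missing atom id",
                     "molecular", _mol_ghost_endpoint),
        MutationSpec("MOL-005", "give a bond three endpoint tokens",
                     "molecular", _mol_three_tokens),
        MutationSpec("DIC-001", "remove the dictionary title", "dictionary",
                     _dic_drop_title),
        MutationSpec("DIC-002", "remove an entry's definition", "dictionary",
                     _dic_drop_definition),
        MutationSpec("DIC-003", "duplicate an entry id", "dictionary",
                     _dic_duplicate_entry),
        MutationSpec("DIC-004", "strip the prefix from an entry's units",
                     "dictionary", _dic_bare_units),
        MutationSpec("DIC-005", "set an entry id to an invalid NCName",
                     "dictionary", _dic_bad_ncname),
        MutationSpec("UTD-001", "remove a unitType entry's dimensions",
                     "unittype_dictionary", _utd_drop_dimension),
        MutationSpec("UND-001", "remove a unit entry's unitType",
                     "unit_dictionary", _und_drop_unittype),
        MutationSpec("UND-002", "remove a unit entry's conversion factor",
                     "unit_dictionary", _und_drop_factor),
        MutationSpec("CC-001", "remove a parameter's dictRef", "compchem",
                     _cc_drop_dictref),
        MutationSpec("CC-002", "remove a parameter's scalar child", "compchem",
                     _cc_drop_scalar),
        MutationSpec("UNI-001", "reference an unknown unit", "units_usage",
                     _uni_unknown_units),
        MutationSpec("UNI-002", "reference a unit without a declared unitType",
                     "units_usage", _uni_typeless_unit),
        MutationSpec("UNI-003", "drop units from a numeric scalar",
                     "units_usage", _uni_drop_units),
    ]
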