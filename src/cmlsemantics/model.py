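"""Generic CML document model and typed views.

The model is deliberately lossless and uninterpreted: every element is a
:class:`CMLNode` carrying its local name, namespace, attributes (as text),
text content and children in document order, together with the accumulated
in-scope ``xmlns`` bindings.  Chemistry-aware behaviour lives in thin views
(:class:`Molecule`, :class:`Atom`, :class:`Bond`, :class:`DataItem`, ...)
that parse numbers and trim token whitespace on access, so a parse →
serialize round trip never alters the document.

Elements outside the CML namespace (e.g. XHTML paragraphs inside dictionary
definitions) are retained as generic nodes, and unknown CML elements are
carried, never dropped: a convention a processor does not understand may be
transparently ignored but must survive re-serialization.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from lxml import etree

from .errors import CMLParseError, ViewError

CML_NS = "http://www.xml-cml.org/schema"
XHTML_NS = "http://www.w3.org/1999/xhtml"

#: Namespaces we expect to see on a document root without warning.
_KNOWN_ROOT_NS = {CML_NS}

_NCNAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def is_ncname(value: str) -> bool:
    """True if *value* is a valid (ASCII) XML NCName: no colon, not starting
    with a digit."""
    return bool(_NCNAME_RE.match(value))


class CMLNamespaceWarning(UserWarning):
    """Root element is not in a recognized namespace (not fatal)."""


@dataclass
class CMLNode:
    """One parsed XML element.

    ``in_scope_bindings`` maps prefix → namespace URI, with the default
    namespace under the empty-string key; a child's bindings contain all of
    its parent's unless shadowed.
    """

    name: str
    namespace_uri: str = ""
    attributes: dict[str, str] = field(default_factory=dict)
    text_content: str = ""
    children: list["CMLNode"] = field(default_factory=list)
    in_scope_bindings: dict[str, str] = field(default_factory=dict)

    # -- structural equality: attribute order ignored (dicts compare by
    #    content), text compared stripped, bindings not compared (they are an
    #    environment, not content).
    def __eq__(self, other) -> bool:
        if not isinstance(other, CMLNode):
            return NotImplemented
        return (
            self.name == other.name
            and self.namespace_uri == other.namespace_uri
            and self.attributes == other.attributes
            and self.text_content.strip() == other.text_content.strip()
            and self.children == other.children
        )

    def get(self, attr: str, default: str | None = None) -> str | None:
        return self.attributes.get(attr, default)

    def child_elements(self, name: str | None = None) -> list["CMLNode"]:
        """Direct children, optionally filtered by local name."""
        if name is None:
            return list(self.children)
        return [c for c in self.children if c.name == name]

    def deep_copy(self) -> "CMLNode":
        return CMLNode(
            name=self.name,
            namespace_uri=self.namespace_uri,
            attributes=dict(self.attributes),
            text_content=self.text_content,
            children=[c.deep_copy() for c in self.children],
            in_scope_bindings=dict(self.in_scope_bindings),
        )

    def all_text(self) -> str:
        """Concatenated text of this element and its descendants."""
        parts = [self.text_content]
        for child in self.children:
            parts.append(child.all_text())
        return " ".join(parts)

    def __repr__(self) -> str:  # keep terse: trees can be large
        return (f"CMLNode({self.name!r}, attrs={len(self.attributes)}, "
                f"children={len(self.children)})")


# ---------------------------------------------------------------------------
# parsing / serialization


def _from_lxml(elem) -> CMLNode:
    qname = etree.QName(elem)
    bindings = {(p if p is not None else ""): uri for p, uri in elem.nsmap.items()}
    attributes: dict[str, str] = {}
    for key, value in elem.attrib.items():
        if key.startswith("{"):
            ns, local = key[1:].split("}", 1)
            prefix = next((p for p, u in elem.nsmap.items() if u == ns and p), None)
            key = f"{prefix}:{local}" if prefix else local
        attributes[key] = value
    children = [_from_lxml(c) for c in elem if isinstance(c.tag, str)]
    return CMLNode(
        name=qname.localname,
        namespace_uri=qname.namespace or "",
        attributes=attributes,
        text_content=elem.text or "",
        children=children,
        in_scope_bindings=bindings,
    )


def read_cml(source) -> CMLNode:
    """Parse CML from a string, bytes, path or file-like object.

    Raises :class:`CMLParseError` (with line number) on malformed XML; a root
    outside the CML namespace is kept but reported via
    :class:`CMLNamespaceWarning`.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:  # path or file-like
            root = etree.parse(str(source) if not hasattr(source, "read")
                               else source).getroot()
    except etree.XMLSyntaxError as exc:
        line = exc.lineno if exc.lineno else None
        raise CMLParseError(str(exc), line=line) from exc
    node = _from_lxml(root)
    if node.namespace_uri not in _KNOWN_ROOT_NS:
        warnings.warn(
            f"document root <{node.name}> is in namespace "
            f"{node.namespace_uri!r}, not the CML namespace",
            CMLNamespaceWarning,
            stacklevel=2,
        )
    return node


def _to_lxml(node: CMLNode, parent_bindings: Mapping[str, str] | None, parent=None):
    nsmap = {(p if p else None): uri for p, uri in node.in_scope_bindings.items()}
    if parent_bindings is not None:
        # declare only bindings new or shadowed relative to the parent
        nsmap = {p: u for p, u in nsmap.items()
                 if parent_bindings.get(p if p else "", None) != u}
    tag = f"{{{node.namespace_uri}}}{node.name}" if node.namespace_uri else node.name
    attrib = {}
    for key, value in node.attributes.items():
        if ":" in key:
            prefix, local = key.split(":", 1)
            ns = node.in_scope_bindings.get(prefix)
            attrib[f"{{{ns}}}{local}" if ns else local] = value
        else:
            attrib[key] = value
    if parent is None:
        elem = etree.Element(tag, attrib=attrib, nsmap=nsmap or None)
    else:
        elem = etree.SubElement(parent, tag, attrib=attrib, nsmap=nsmap or None)
    elem.text = node.text_content or None
    for child in node.children:
        _to_lxml(child, node.in_scope_bindings, parent=elem)
    return elem


def write_cml(node: CMLNode) -> str:
    """Serialize to namespace-correct XML text; ``read_cml(write_cml(n)) == n``."""
    elem = _to_lxml(node, None)
    return etree.tostring(
        elem, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# traversal


def walk(node: CMLNode) -> Iterator[tuple[str, CMLNode, tuple[CMLNode, ...]]]:
    """Depth-first document-order walk yielding (path, node, ancestors).

    Paths are XPath-like with 1-based same-name sibling indices, e.g.
    ``/fragment/molecule[1]/atomArray[1]/atom[3]``; the root carries no index.
    """

    def _walk(current, path, ancestors):
        yield path, current, ancestors
        counts: dict[str, int] = {}
        for child in current.children:
            counts[child.name] = counts.get(child.name, 0) + 1
            child_path = f"{path}/{child.name}[{counts[child.name]}]"
            yield from _walk(child, child_path, ancestors + (current,))

    yield from _walk(node, f"/{node.name}", ())


def find_all(node: CMLNode, name: str) -> list[CMLNode]:
    """All elements with local *name* at any depth (including the root),
    in document order."""
    return [n for _, n, _ in walk(node) if n.name == name]


def node_path(root: CMLNode, target: CMLNode) -> str | None:
    """Path of *target* (by identity) within *root*, or None."""
    for path, node, _ in walk(root):
        if node is target:
            return path
    return None


# ---------------------------------------------------------------------------
# typed views


def _float_or_none(text: str | None) -> float | None:
    return None if text is None else float(text)


def _int_or_none(text: str | None) -> int | None:
    return None if text is None else int(text)


class _View:
    """Base for typed views: shares the underlying node, never copies."""

    _element_names: tuple[str, ...] = ()

    def __init__(self, node: CMLNode):
        if node.name not in self._element_names:
            raise ViewError(
                f"cannot view <{node.name}> as {type(self).__name__} "
                f"(expected {' or '.join(self._element_names)})"
            )
        self.node = node


class Atom(_View):
    _element_names = ("atom",)

    @property
    def id(self) -> str | None:
        return self.node.get("id")

    @property
    def element_type(self) -> str | None:
        return self.node.get("elementType")

    @property
    def x3(self) -> float | None:
        return _float_or_none(self.node.get("x3"))

    @property
    def y3(self) -> float | None:
        return _float_or_none(self.node.get("y3"))

    @property
    def z3(self) -> float | None:
        return _float_or_none(self.node.get("z3"))

    @property
    def formal_charge(self) -> int | None:
        return _int_or_none(self.node.get("formalCharge"))

    @property
    def hydrogen_count(self) -> int | None:
        return _int_or_none(self.node.get("hydrogenCount"))

    @property
    def labels(self) -> list[tuple[str | None, str]]:
        """(dictRef, value) pairs from child label elements; token text is
        trimmed (the common serialization pads it with spaces)."""
        return [(lab.get("dictRef"), lab.text_content.strip())
                for lab in self.node.child_elements("label")]


class Bond(_View):
    _element_names = ("bond",)

    @property
    def id(self) -> str | None:
        return self.node.get("id")

    @property
    def atom_refs2(self) -> tuple[str, str] | None:
        """The two referenced atom ids, or None if absent or not two tokens."""
        raw = self.node.get("atomRefs2")
        if raw is None:
            return None
        tokens = raw.split()
        return (tokens[0], tokens[1]) if len(tokens) == 2 else None

    @property
    def order(self) -> str | None:
        # uninterpreted token: the community uses both "1"/"2" and "S"
        return self.node.get("order")


def _local_descendants(node: CMLNode, name: str) -> list[CMLNode]:
    """Descendants with local *name* that are not inside a nested molecule."""
    found: list[CMLNode] = []
    for child in node.children:
        if child.name == name:
            found.append(child)
        if child.name != "molecule":
            found.extend(_local_descendants(child, name))
    return found


class Molecule(_View):
    _element_names = ("molecule",)

    @property
    def id(self) -> str | None:
        return self.node.get("id")

    @property
    def role(self) -> str | None:
        return self.node.get("role")

    @property
    def atoms(self) -> list[Atom]:
        """Atoms of this molecule (via atomArray or direct), excluding those
        of nested child molecules."""
        return [Atom(n) for n in _local_descendants(self.node, "atom")]

    @property
    def bonds(self) -> list[Bond]:
        return [Bond(n) for n in _local_descendants(self.node, "bond")]

    @property
    def child_molecules(self) -> list["Molecule"]:
        mols = []
        for child in self.node.children:
            if child.name == "molecule":
                mols.append(Molecule(child))
            else:
                mols.extend(Molecule(n) for n in find_all(child, "molecule"))
        return mols


class DataItem(_View):
    """View over scalar / array / matrix data carriers."""

    _element_names = ("scalar", "array", "matrix")

    @property
    def kind(self) -> str:
        return self.node.name

    @property
    def dict_ref(self) -> str | None:
        return self.node.get("dictRef")

    @property
    def data_type(self) -> str | None:
        return self.node.get("dataType")

    @property
    def units(self) -> str | None:
        return self.node.get("units")

    @property
    def unit_type(self) -> str | None:
        return self.node.get("unitType")

    @property
    def values(self) -> list[str]:
        """Whitespace-split value tokens; a scalar yields exactly one
        (trimmed, may be empty)."""
        text = self.node.text_content
        if self.kind == "scalar":
            return [text.strip()]
        return text.split()


class _DictRefContainer(_View):
    @property
    def dict_ref(self) -> str | None:
        return self.node.get("dictRef")

    @property
    def data_items(self) -> list[DataItem]:
        return [DataItem(n) for n in self.node.children
                if n.name in DataItem._element_names]


class Property(_DictRefContainer):
    _element_names = ("property",)


class Parameter(_DictRefContainer):
    _element_names = ("parameter",)


def as_molecule(node: CMLNode) -> Molecule:
    return Molecule(node)


def as_dataitem(node: CMLNode) -> DataItem:
    return DataItem(node)
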