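"""Scientific units: dimension vectors, unit definitions and conversion.

A *unitType* names the kind of quantity a unit measures and carries a
:class:`Dimension`: a vector of rational exponents over the seven SI base
quantities, extended with non-cancelling annotation tags.  The tags carry
experimental semantics that plain dimensional analysis loses: mg (drug) per
kg (animal) has all-zero exponents but is *not* a pure number, because
``drug`` and ``animal`` do not cancel; likewise ppm is dimensionless-with-
annotation and distinct from a bare ratio.

A *unit* is an instance of a unitType scaled to the SI-coherent base of its
dimension: ``x_SI = value * factor_to_base + offset_to_base``, with a
nonzero offset allowed only for pure-temperature units (Celsius).  Unit
conversion therefore requires equal dimensions — exponents *and* annotation
multisets — and is exact function composition through the base.

The dalton is deliberately registered twice: as a molecular mass
(1 g/mol divided by the Avogadro constant, about 1.66e-27 kg) and as a
molar mass (1 Da = 1 g/mol, factor exactly that of gram-per-mole).  The
requested target's unitType disambiguates, mirroring the long-standing
molecular-mass/molar-mass confusion around this unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

from .conventions import ERROR, WARNING, ValidationIssue, validate
from .errors import (
    AffineUnitError,
    CMLError,
    IncompatibleUnitsError,
    MalformedReferenceError,
    UnboundPrefixError,
    UnknownPrefixError,
    UnknownUnitError,
)
from .model import CMLNode, DataItem, read_cml, walk
from .refs import Catalog, QRef, default_catalog, parse_qref, resolve_qref

#: The seven SI base quantities, in conventional order.
BASE_QUANTITIES = (
    "length",
    "mass",
    "time",
    "electric_current",
    "temperature",
    "amount_of_substance",
    "luminous_intensity",
)

#: Avogadro constant (CODATA 2006), 1/mol: the value fixing the dalton's
#: mass reading at (1 g/mol) / N_A.
AVOGADRO_2006 = 6.02214179e23

#: The 20 SI multiplier prefixes and their powers of ten.
SI_PREFIXES = {
    "yotta": 24, "zetta": 21, "exa": 18, "peta": 15, "tera": 12,
    "giga": 9, "mega": 6, "kilo": 3, "hecto": 2, "deca": 1,
    "deci": -1, "centi": -2, "milli": -3, "micro": -6, "nano": -9,
    "pico": -12, "femto": -15, "atto": -18, "zepto": -21, "yocto": -24,
}

UNITTYPE_NS = "http://www.xml-cml.org/unit/unitType/"
SI_NS = "http://www.xml-cml.org/unit/si/"
NONSI_NS = "http://www.xml-cml.org/unit/nonSi/"


class DimensionSyntaxError(CMLError):
    """A dimension declaration string cannot be parsed."""


@dataclass(frozen=True)
class Dimension:
    """Rational exponents over the SI base quantities plus annotation
    multisets (numerator/denominator) that never cancel implicitly."""

    exponents: tuple[tuple[str, Fraction], ...] = ()
    annotations_num: tuple[tuple[str, int], ...] = ()
    annotations_den: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def create(exponents: Mapping[str, Fraction | int] | None = None,
               annotations_num: Iterable[str] | Mapping[str, int] = (),
               annotations_den: Iterable[str] | Mapping[str, int] = ()) -> "Dimension":
        exps = {}
        for name, power in (exponents or {}).items():
            if name not in BASE_QUANTITIES:
                raise DimensionSyntaxError(f"unknown base quantity {name!r}")
            power = Fraction(power)
            if power:
                exps[name] = power
        num = Counter(annotations_num)
        den = Counter(annotations_den)
        return Dimension(
            exponents=tuple(sorted(exps.items())),
            annotations_num=tuple(sorted(num.items())),
            annotations_den=tuple(sorted(den.items())),
        )

    # -- views -------------------------------------------------------------
    def exponent(self, quantity: str) -> Fraction:
        return dict(self.exponents).get(quantity, Fraction(0))

    @property
    def is_pure_dimensionless(self) -> bool:
        return not self.exponents and not self.annotations_num and not self.annotations_den

    @property
    def is_pure_temperature(self) -> bool:
        return (self.exponents == (("temperature", Fraction(1)),)
                and not self.annotations_num and not self.annotations_den)

    # -- algebra -----------------------------------------------------------
    def __mul__(self, other: "Dimension") -> "Dimension":
        exps = Counter(dict(self.exponents))
        for name, power in other.exponents:
            exps[name] += power
        return Dimension.create(
            {n: p for n, p in exps.items() if p},
            Counter(dict(self.annotations_num)) + Counter(dict(other.annotations_num)),
            Counter(dict(self.annotations_den)) + Counter(dict(other.annotations_den)),
        )

    def __truediv__(self, other: "Dimension") -> "Dimension":
        # divisor's numerator tags land in our denominator and vice versa;
        # shared tags do NOT cancel unless normalize() is called explicitly
        exps = Counter(dict(self.exponents))
        for name, power in other.exponents:
            exps[name] -= power
        return Dimension.create(
            {n: p for n, p in exps.items() if p},
            Counter(dict(self.annotations_num)) + Counter(dict(other.annotations_den)),
            Counter(dict(self.annotations_den)) + Counter(dict(other.annotations_num)),
        )

    def normalize(self) -> "Dimension":
        """Explicitly cancel annotation tags present in both numerator and
        denominator (never done implicitly)."""
        num = Counter(dict(self.annotations_num))
        den = Counter(dict(self.annotations_den))
        for tag in set(num) & set(den):
            shared = min(num[tag], den[tag])
            num[tag] -= shared
            den[tag] -= shared
        return Dimension.create(dict(self.exponents),
                                +num, +den)

    def __str__(self) -> str:
        parts = [f"{n}:{p}" for n, p in self.exponents]
        parts += [f"@{t}:{c}" for t, c in self.annotations_num]
        parts += [f"@{t}:-{c}" for t, c in self.annotations_den]
        return " ".join(parts) if parts else "dimensionless"


DIMENSIONLESS = Dimension.create()


def dim_mul(a: Dimension, b: Dimension) -> Dimension:
    return a * b


def dim_div(a: Dimension, b: Dimension) -> Dimension:
    return a / b


def dim_eq(a: Dimension, b: Dimension) -> bool:
    return a == b


def parse_dimension(text: str) -> Dimension:
    """Parse the declaration encoding used in unitType dictionaries:
    whitespace-separated ``quantity:exponent`` tokens (``@tag:count`` for
    annotations, negative counts denoting the denominator); the empty string
    is pure dimensionless.  See docs/formats.md."""
    exps: dict[str, Fraction] = {}
    num: Counter = Counter()
    den: Counter = Counter()
    for token in text.split():
        if ":" not in token:
            raise DimensionSyntaxError(f"token {token!r} lacks ':exponent'")
        name, _, raw = token.rpartition(":")
        try:
            power = Fraction(raw)
        except (ValueError, ZeroDivisionError) as exc:
            raise DimensionSyntaxError(f"bad exponent in {token!r}") from exc
        if name.startswith("@"):
            tag = name[1:]
            if not tag or power.denominator != 1:
                raise DimensionSyntaxError(f"bad annotation token {token!r}")
            if power > 0:
                num[tag] += int(power)
            elif power < 0:
                den[tag] += int(-power)
        elif name in BASE_QUANTITIES:
            exps[name] = exps.get(name, Fraction(0)) + power
        else:
            raise DimensionSyntaxError(f"unknown base quantity {name!r}")
    return Dimension.create(exps, num, den)


# ---------------------------------------------------------------------------
# definitions and registry


@dataclass(frozen=True)
class UnitTypeDef:
    id: str
    dimension: Dimension


@dataclass(frozen=True)
class UnitDef:
    """A unit as a scaled (optionally affine) instance of its unitType."""

    id: str
    unit_type: str | None          # QRef text, e.g. "unitType:mass"
    factor_to_base: float
    offset_to_base: float = 0.0

    def __post_init__(self):
        if not self.factor_to_base > 0:
            raise CMLError(f"unit {self.id!r}: factor_to_base must be positive")


@dataclass
class Quantity:
    """The product of numerical value(s) and a unit."""

    values: list[float]
    unit: str

    def __init__(self, values, unit):
        self.values = [float(values)] if isinstance(values, (int, float)) else [
            float(v) for v in values]
        self.unit = str(unit)

    @property
    def value(self) -> float:
        if len(self.values) != 1:
            raise CMLError("quantity is not scalar")
        return self.values[0]


class UnitsRegistry:
    """Index of unitType and unit definitions keyed by absolute URI.

    Several :class:`UnitDef` registrations may share one URI (the dalton's
    dual mass/molar-mass reading); conversion disambiguates them by matching
    dimensions against the other side.
    """

    def __init__(self, catalog: Catalog | None = None):
        self.catalog = catalog if catalog is not None else default_catalog()
        self.unit_types: dict[str, UnitTypeDef] = {}
        self.units: dict[str, list[UnitDef]] = {}

    # -- registration ------------------------------------------------------
    def add_unit_type(self, definition: UnitTypeDef,
                      namespace: str = UNITTYPE_NS) -> None:
        self.unit_types[namespace + definition.id] = definition

    def add_unit(self, definition: UnitDef, namespace: str = NONSI_NS) -> None:
        dimension = self.dimension_of(definition)
        if definition.offset_to_base and not (
                dimension is not None and dimension.is_pure_temperature):
            raise AffineUnitError(
                f"unit {definition.id!r}: offsets are allowed only for "
                f"pure-temperature units")
        self.units.setdefault(namespace + definition.id, []).append(definition)

    # -- resolution --------------------------------------------------------
    def _to_uri(self, ref, bindings: Mapping[str, str] | None = None) -> str:
        if isinstance(ref, QRef):
            return resolve_qref(ref, bindings or {}, self.catalog)
        if isinstance(ref, str) and "://" in ref:
            return ref
        try:
            return resolve_qref(parse_qref(ref), bindings or {}, self.catalog)
        except (MalformedReferenceError, UnboundPrefixError) as exc:
            raise UnknownUnitError(f"cannot resolve unit reference {ref!r}: {exc}") from exc

    def resolve_unit(self, ref, bindings: Mapping[str, str] | None = None) -> list[UnitDef]:
        uri = self._to_uri(ref, bindings)
        try:
            return self.units[uri]
        except KeyError:
            raise UnknownUnitError(f"no unit registered at {uri}") from None

    def unit_type_def(self, unit: UnitDef) -> UnitTypeDef | None:
        if unit.unit_type is None:
            return None
        try:
            return self.unit_types.get(self._to_uri(unit.unit_type))
        except UnknownUnitError:
            return None

    def dimension_of(self, unit: UnitDef) -> Dimension | None:
        type_def = self.unit_type_def(unit)
        return None if type_def is None else type_def.dimension


# ---------------------------------------------------------------------------
# conversion


def convert(quantity: Quantity, target_unit, registry: UnitsRegistry,
            bindings: Mapping[str, str] | None = None) -> Quantity:
    """Convert a quantity to *target_unit* through the SI-coherent base.

    Requires a source/target registration pair of equal dimension
    (exponents and annotation multisets); each value maps as
    ``((v * f_src + o_src) - o_tgt) / f_tgt``.
    """
    sources = registry.resolve_unit(quantity.unit, bindings)
    targets = registry.resolve_unit(target_unit, bindings)
    chosen = None
    for src in sources:
        for tgt in targets:
            dim_src = registry.dimension_of(src)
            dim_tgt = registry.dimension_of(tgt)
            if dim_src is not None and dim_src == dim_tgt:
                chosen = (src, tgt)
                break
        if chosen:
            break
    if chosen is None:
        described = " / ".join(
            f"{u.id}[{registry.dimension_of(u)}]" for u in sources + targets)
        raise IncompatibleUnitsError(
            f"no dimensionally compatible reading: {described}")
    src, tgt = chosen
    converted = [
        ((v * src.factor_to_base + src.offset_to_base) - tgt.offset_to_base)
        / tgt.factor_to_base
        for v in quantity.values
    ]
    return Quantity(converted, str(target_unit))


def apply_prefix(unit: UnitDef, prefix: str) -> UnitDef:
    """Scale a unit by one of the 20 SI multiplier prefixes (affine units
    cannot be prefixed)."""
    if prefix not in SI_PREFIXES:
        raise UnknownPrefixError(f"unknown SI prefix {prefix!r}")
    if unit.offset_to_base:
        raise AffineUnitError(f"cannot prefix affine unit {unit.id!r}")
    return replace(unit, id=prefix + unit.id,
                   factor_to_base=unit.factor_to_base * 10.0 ** SI_PREFIXES[prefix])


# ---------------------------------------------------------------------------
# loading unit dictionaries from CML


def load_unittype_dictionary(source, registry: UnitsRegistry) -> None:
    """Load a unitType dictionary (validated by its own convention rules)
    into the registry."""
    doc = source if isinstance(source, CMLNode) else read_cml(source)
    report = validate(doc, catalog=registry.catalog)
    if not report.conformant:
        from .errors import DictionaryLoadError
        raise DictionaryLoadError("unitType dictionary failed validation", report)
    namespace = doc.get("namespace", UNITTYPE_NS)
    for entry in doc.child_elements("entry"):
        registry.add_unit_type(
            UnitTypeDef(entry.get("id"), parse_dimension(entry.get("dimension", ""))),
            namespace=namespace,
        )


def load_unit_dictionary(source, registry: UnitsRegistry) -> None:
    """Load a unit dictionary; ``altUnitType``/``altMultiplierToSI`` emit a
    second registration for the same unit id (the dalton's dual reading)."""
    doc = source if isinstance(source, CMLNode) else read_cml(source)
    report = validate(doc, catalog=registry.catalog)
    if not report.conformant:
        from .errors import DictionaryLoadError
        raise DictionaryLoadError("unit dictionary failed validation", report)
    namespace = doc.get("namespace", NONSI_NS)
    for entry in doc.child_elements("entry"):
        registry.add_unit(
            UnitDef(
                id=entry.get("id"),
                unit_type=entry.get("unitType"),
                factor_to_base=float(entry.get("multiplierToSI")),
                offset_to_base=float(entry.get("constantToSI", "0") or 0),
            ),
            namespace=namespace,
        )
        if entry.get("altUnitType"):
            registry.add_unit(
                UnitDef(
                    id=entry.get("id"),
                    unit_type=entry.get("altUnitType"),
                    factor_to_base=float(entry.get("altMultiplierToSI")),
                ),
                namespace=namespace,
            )


def default_units_registry(catalog: Catalog | None = None) -> UnitsRegistry:
    """Registry loaded from the curated unitType/SI/non-SI dictionaries
    shipped with the package."""
    registry = UnitsRegistry(catalog)
    from importlib.resources import files

    data = files("cmlsemantics") / "data"
    load_unittype_dictionary(str(data / "unittype_dictionary.xml"), registry)
    load_unit_dictionary(str(data / "si_units.xml"), registry)
    load_unit_dictionary(str(data / "nonsi_units.xml"), registry)
    return registry


# ---------------------------------------------------------------------------
# document-level checks

_NUMERIC_DATATYPE_LOCALS = {"double", "float", "decimal", "integer", "int", "long"}


def _is_numeric_datatype(data_type: str | None) -> bool:
    if data_type is None:
        return False
    local = data_type.rsplit(":", 1)[-1]
    return local in _NUMERIC_DATATYPE_LOCALS


def check_units_usage(
    doc: CMLNode,
    units_registry: UnitsRegistry,
    catalog: Catalog | None = None,
    dictionary_registry=None,
) -> list[ValidationIssue]:
    """Audit every scalar/array/matrix for units hygiene.

    UNI-001: the units reference resolves to no registered unit.
    UNI-002: the unit resolves but its unitType (hence dimension) is
    undeclared.
    UNI-003 (warning): numeric dataType with no units attribute.

    With a dictionary registry supplied, dictRef'd items are additionally
    cross-checked against their entries (DAT-xxx issues).
    """
    if catalog is None:
        catalog = units_registry.catalog
    issues: list[ValidationIssue] = []
    for path, node, _ in walk(doc):
        if node.name not in DataItem._element_names:
            continue
        item = DataItem(node)
        if item.units is not None:
            try:
                defs = units_registry.resolve_unit(item.units,
                                                   node.in_scope_bindings)
            except UnknownUnitError as exc:
                issues.append(ValidationIssue(ERROR, "UNI-001", path, str(exc)))
                defs = None
            if defs is not None and all(
                    units_registry.dimension_of(u) is None for u in defs):
                issues.append(ValidationIssue(
                    ERROR, "UNI-002", path,
                    f"unit {item.units!r} has no resolvable unitType/dimension"))
        elif _is_numeric_datatype(item.data_type):
            issues.append(ValidationIssue(
                WARNING, "UNI-003", path,
                f"numeric {item.kind} ({item.data_type}) has no units attribute"))
        if dictionary_registry is not None and item.dict_ref is not None:
            from .dictionary import check_data
            from .errors import MissingEntryError, UnknownDictionaryError
            try:
                entry = dictionary_registry.lookup(item.dict_ref,
                                                   bindings=node.in_scope_bindings)
            except (UnknownDictionaryError, MissingEntryError):
                continue
            issues.extend(check_data(entry=entry, item=item,
                                     units_registry=units_registry, path=path))
    return issues
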