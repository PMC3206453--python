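"""Dimension algebra, unit conversion and units-usage auditing."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmlsemantics.errors import (
    AffineUnitError,
    IncompatibleUnitsError,
    UnknownPrefixError,
    UnknownUnitError,
)
from cmlsemantics.model import CML_NS, read_cml
from cmlsemantics.units import (
    AVOGADRO_2006,
    BASE_QUANTITIES,
    DIMENSIONLESS,
    Dimension,
    DimensionSyntaxError,
    Quantity,
    UnitDef,
    apply_prefix,
    check_units_usage,
    convert,
    dim_div,
    dim_eq,
    dim_mul,
    parse_dimension,
)

MASS = Dimension.create({"mass": 1})
LENGTH = Dimension.create({"length": 1})

dimensions = st.builds(
    Dimension.create,
    st.dictionaries(st.sampled_from(BASE_QUANTITIES),
                    st.integers(-3, 3), max_size=4),
    st.lists(st.sampled_from(["drug", "animal", "part", "whole"]), max_size=3),
    st.lists(st.sampled_from(["drug", "animal", "part", "whole"]), max_size=3),
)


class TestDimensionAlgebra:
    def test_drug_per_animal_is_not_dimensionless(self):
        dose = dim_div(Dimension.create({"mass": 1}, ["drug"]),
                       Dimension.create({"mass": 1}, ["animal"]))
        assert all(dose.exponent(q) == 0 for q in BASE_QUANTITIES)
        assert dict(dose.annotations_num) == {"drug": 1}
        assert dict(dose.annotations_den) == {"animal": 1}
        assert not dose.is_pure_dimensionless
        assert not dim_eq(dose, DIMENSIONLESS)

    def test_self_division_without_annotations_is_identity(self):
        d = Dimension.create({"length": 2, "time": -1})
        assert dim_div(d, d) == DIMENSIONLESS

    def test_annotated_dimensionless_differs_from_plain(self):
        ppm = parse_dimension("@part:1 @whole:-1")
        assert not dim_eq(ppm, DIMENSIONLESS)
        assert dim_eq(ppm, ppm)

    def test_annotations_cancel_only_on_request(self):
        ratio = dim_div(Dimension.create({}, ["drug"]),
                        Dimension.create({}, ["drug"]))
        assert not ratio.is_pure_dimensionless
        assert ratio.normalize().is_pure_dimensionless

    def test_rational_exponents(self):
        half = parse_dimension("time:-1/2")
        assert dim_mul(half, half) == parse_dimension("time:-1")

    @pytest.mark.parametrize("bad", ["mass", "spin:1", "@:1", "mass:x"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(DimensionSyntaxError):
            parse_dimension(bad)

    def test_declaration_roundtrip(self):
        d = parse_dimension("mass:1 amount_of_substance:-1 @drug:1")
        assert parse_dimension(str(d)) == d

    @given(dimensions, dimensions, dimensions)
    def test_group_laws(self, a, b, c):
        assert dim_mul(a, b) == dim_mul(b, a)
        assert dim_mul(dim_mul(a, b), c) == dim_mul(a, dim_mul(b, c))
        assert dim_mul(a, DIMENSIONLESS) == a


class TestConversion:
    def test_dalton_to_kilogram_nine_significant_figures(self, units_registry):
        result = convert(Quantity(1.0, "unit:dalton"), "si:kilogram",
                         units_registry)
        assert result.value == pytest.approx(1.660538782e-27, rel=5e-10)
        # and the factor is exactly (1 g/mol) / N_A
        assert result.value == pytest.approx(1e-3 / AVOGADRO_2006, rel=1e-15)

    def test_dalton_molar_mass_reading_is_unity(self, units_registry):
        result = convert(Quantity(1.0, "unit:dalton"), "unit:gramPerMole",
                         units_registry)
        assert result.value == 1.0

    def test_annotations_block_conversion(self, units_registry):
        with pytest.raises(IncompatibleUnitsError):
            convert(Quantity(5.0, "unit:mgPerKgBodyMass"), "unit:perMille",
                    units_registry)

    def test_plain_dimension_mismatch(self, units_registry):
        with pytest.raises(IncompatibleUnitsError):
            convert(Quantity(1.0, "si:metre"), "si:kilogram", units_registry)

    def test_unknown_unit(self, units_registry):
        with pytest.raises(UnknownUnitError):
            convert(Quantity(1.0, "unit:cubit"), "si:metre", units_registry)

    def test_affine_celsius(self, units_registry):
        assert convert(Quantity(25.0, "si:celsius"), "si:kelvin",
                       units_registry).value == pytest.approx(298.15)
        assert convert(Quantity(273.15, "si:kelvin"), "si:celsius",
                       units_registry).value == pytest.approx(0.0, abs=1e-12)

    def test_array_payload_converts_elementwise(self, units_registry):
        result = convert(Quantity([1.0, 2.5], "unit:angstrom"), "si:metre",
                         units_registry)
        assert result.values == pytest.approx([1.0e-10, 2.5e-10])

    def test_roundtrip_identity_all_compatible_pairs(self, units_registry):
        """value -> other unit -> back reproduces the value to 1e-12
        relative error for every non-affine pair of equal dimension."""
        flat = [(uri, u) for uri, defs in units_registry.units.items()
                for u in defs if u.offset_to_base == 0]
        checked = 0
        for (uri_a, a), (uri_b, b) in itertools.permutations(flat, 2):
            dim_a = units_registry.dimension_of(a)
            if dim_a is None or dim_a != units_registry.dimension_of(b):
                continue
            q = Quantity(3.7, uri_a)
            back = convert(convert(q, uri_b, units_registry), uri_a,
                           units_registry)
            assert back.value == pytest.approx(3.7, rel=1e-12)
            checked += 1
        assert checked >= 6

    def test_conversion_composes_through_intermediate(self, units_registry):
        direct = convert(Quantity(2.0, "unit:dalton"), "si:gram",
                         units_registry)
        via_kg = convert(
            convert(Quantity(2.0, "unit:dalton"), "si:kilogram", units_registry),
            "si:gram", units_registry)
        assert via_kg.value == pytest.approx(direct.value, rel=1e-12)


class TestPrefixes:
    def test_milli_gram(self, units_registry):
        gram = units_registry.resolve_unit("si:gram")[0]
        milligram = apply_prefix(gram, "milli")
        assert milligram.id == "milligram"
        assert milligram.factor_to_base == pytest.approx(1e-6)

    def test_kilo_gram_restores_coherent_base(self, units_registry):
        gram = units_registry.resolve_unit("si:gram")[0]
        assert apply_prefix(gram, "kilo").factor_to_base == pytest.approx(1.0)

    def test_unknown_prefix(self, units_registry):
        metre = units_registry.resolve_unit("si:metre")[0]
        with pytest.raises(UnknownPrefixError):
            apply_prefix(metre, "myria")

    def test_affine_units_cannot_be_prefixed(self, units_registry):
        celsius = units_registry.resolve_unit("si:celsius")[0]
        with pytest.raises(AffineUnitError):
            apply_prefix(celsius, "milli")

    def test_twenty_prefixes(self):
        from cmlsemantics.units import SI_PREFIXES
        assert len(SI_PREFIXES) == 20


class TestIndependentOracle:
    """Cross-check conversion factors against scipy.constants (CODATA).

    The dalton is compared loosely: this package pins the printed 2006
    Avogadro constant, scipy carries the current CODATA adjustment.
    """

    def test_factors_match_scipy_constants(self, units_registry):
        from scipy import constants

        gram = units_registry.resolve_unit("si:gram")[0]
        oracle = [
            ("si:metre", None, 1.0),
            ("si:kilogram", None, 1.0),
            ("si:second", None, 1.0),
            ("si:kelvin", None, 1.0),
            ("si:mole", None, 1.0),
            ("si:ampere", None, 1.0),
            ("si:candela", None, 1.0),
            ("si:gram", None, constants.gram),
            ("unit:angstrom", None, constants.angstrom),
            ("unit:litre", None, constants.liter),
            ("unit:ppm", None, 1e-6),
            (None, apply_prefix(gram, "milli"), constants.milli * constants.gram),
            (None, apply_prefix(gram, "micro"), constants.micro * constants.gram),
            (None, apply_prefix(gram, "kilo"), constants.kilo * constants.gram),
            (None, apply_prefix(units_registry.resolve_unit("si:metre")[0],
                                "centi"), constants.centi),
            (None, apply_prefix(units_registry.resolve_unit("si:metre")[0],
                                "nano"), constants.nano),
            (None, apply_prefix(units_registry.resolve_unit("si:second")[0],
                                "pico"), constants.pico),
            (None, apply_prefix(units_registry.resolve_unit("si:second")[0],
                                "femto"), constants.femto),
            (None, apply_prefix(units_registry.resolve_unit("si:metre")[0],
                                "mega"), constants.mega),
            (None, apply_prefix(units_registry.resolve_unit("si:mole")[0],
                                "milli"), constants.milli),
        ]
        assert len(oracle) == 20
        for ref, unit, expected in oracle:
            if unit is None:
                unit = units_registry.resolve_unit(ref)[0]
            assert unit.factor_to_base == pytest.approx(expected, rel=1e-9)

        dalton = units_registry.resolve_unit("unit:dalton")[0]
        assert dalton.factor_to_base == pytest.approx(
            constants.atomic_mass, rel=1e-5)
        celsius = units_registry.resolve_unit("si:celsius")[0]
        assert celsius.offset_to_base == pytest.approx(constants.zero_Celsius)


class TestUnitsUsage:
    def scalar_doc(self, attrs):
        parts = " ".join(f"{k}='{v}'" for k, v in attrs.items())
        return read_cml(
            f"<cml xmlns='{CML_NS}' "
            f"xmlns:unit='http://www.xml-cml.org/unit/nonSi/' "
            f"xmlns:xsd='http://www.w3.org/2001/XMLSchema'>"
            f"<scalar {parts}>1.0</scalar></cml>")

    def test_clean_document(self, units_registry):
        doc = self.scalar_doc({"dataType": "xsd:double", "units": "unit:dalton"})
        assert check_units_usage(doc, units_registry) == []

    def test_unregistered_unit(self, units_registry):
        from cmlsemantics.units import UnitsRegistry
        doc = self.scalar_doc({"units": "unit:dalton"})
        empty = UnitsRegistry(units_registry.catalog)
        issues = check_units_usage(doc, empty)
        assert [i.rule_code for i in issues] == ["UNI-001"]

    def test_numeric_scalar_without_units_warns(self, units_registry):
        doc = self.scalar_doc({"dataType": "xsd:double"})
        issues = check_units_usage(doc, units_registry)
        assert [(i.severity, i.rule_code) for i in issues] == [
            ("warning", "UNI-003")]

    def test_string_scalar_without_units_is_fine(self, units_registry):
        doc = self.scalar_doc({"dataType": "xsd:string"})
        assert check_units_usage(doc, units_registry) == []

    def test_dictref_cross_check(self, units_registry, dict_registry):
        doc = self.scalar_doc({"dataType": "xsd:double",
                               "dictRef": "dummy:molecmass"})
        issues = check_units_usage(doc, units_registry,
                                   dictionary_registry=dict_registry)
        codes = [i.rule_code for i in issues]
        assert "UNI-003" in codes and "DAT-004" in codes
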