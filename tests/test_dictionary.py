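"""Dictionary loading, lookup, data checking, harvesting and scaffolding."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmlsemantics.conventions import validate
from cmlsemantics.dictionary import (
    DictionaryRegistry,
    STUB_DEFINITION,
    build_stub_dictionary,
    check_data,
    effective_units,
    harvest_report_tsv,
    harvest_terms,
    load_dictionary,
)
from cmlsemantics.errors import (
    DictionaryLoadError,
    MissingEntryError,
    UnknownDictionaryError,
)
from cmlsemantics.model import CML_NS, DataItem, read_cml, write_cml
from cmlsemantics.fixtures import generate_compchem_corpus

EMPTY_DICT = (
    "<dictionary xmlns='%s' "
    "xmlns:convention='http://www.xml-cml.org/convention/' "
    "convention='convention:dictionary' title='empty' "
    "namespace='http://example.org/empty/' dictionaryPrefix='empty'/>" % CML_NS
)


def scalar_item(text, **attrs):
    parts = " ".join(f"{k}='{v}'" for k, v in attrs.items())
    node = read_cml(
        f"<scalar xmlns='{CML_NS}' "
        f"xmlns:unit='http://www.xml-cml.org/unit/nonSi/' "
        f"xmlns:unitType='http://www.xml-cml.org/unit/unitType/' "
        f"xmlns:xsd='http://www.w3.org/2001/XMLSchema' {parts}>{text}</scalar>")
    return DataItem(node)


class TestLoadDictionary:
    def test_dummy_dictionary(self, dummy_dictionary):
        doc = load_dictionary(dummy_dictionary)
        assert doc.prefix == "dummy"
        assert set(doc.entries) == {"molecmass", "molarmass"}
        assert doc.entries["molarmass"].definition == (
            "The mass per amount of substance.")
        entry = doc.entries["molecmass"]
        assert entry.term == "Molecular Mass"
        assert entry.data_type == "xsd:double"
        assert entry.default_units == "unit:dalton"

    def test_invalid_dictionary_refused_with_report(self, dummy_dictionary):
        del dummy_dictionary.attributes["dictionaryPrefix"]
        with pytest.raises(DictionaryLoadError) as err:
            load_dictionary(dummy_dictionary)
        assert "DIC-001" in err.value.report.rule_codes()

    def test_empty_dictionary_loads(self):
        assert load_dictionary(read_cml(EMPTY_DICT)).entries == {}

    def test_load_write_load_idempotent(self, dummy_dictionary):
        once = load_dictionary(dummy_dictionary)
        twice = load_dictionary(read_cml(write_cml(once.to_cml())))
        assert list(twice.entries) == list(once.entries)
        assert twice.entries["molecmass"].definition == (
            once.entries["molecmass"].definition)


class TestLookup:
    def test_direct_hit(self, dict_registry):
        assert dict_registry.lookup("dummy:molecmass").term == "Molecular Mass"

    def test_uri_form(self, dict_registry):
        entry = dict_registry.lookup(
            "http://www.xml-cml.org/dictionary/dummy/molarmass")
        assert entry.id == "molarmass"

    def test_missing_entry(self, dict_registry):
        with pytest.raises(MissingEntryError):
            dict_registry.lookup("dummy:nonexistent")

    def test_unknown_dictionary(self, dict_registry):
        with pytest.raises(UnknownDictionaryError):
            dict_registry.lookup("http://example.org/nowhere/x")

    def test_parent_chain_fallback(self):
        parent = build_stub_dictionary(
            ["energy", "gradient"], "http://example.org/compchem/", "ccm")
        child = build_stub_dictionary(
            ["specialKeyword"], "http://example.org/mycode/", "mycode")
        registry = DictionaryRegistry()
        registry.add(parent)
        registry.add(child, parent_namespace="http://example.org/compchem/")
        # child lacks 'energy': the common compchem parent supplies it
        assert registry.lookup("http://example.org/mycode/energy").id == "energy"
        assert registry.lookup("http://example.org/mycode/specialKeyword").id == (
            "specialKeyword")

    def test_hierarchy_equals_flat_when_no_parent(self):
        flat = DictionaryRegistry()
        doc = build_stub_dictionary(["a", "b"], "http://example.org/d/", "d")
        flat.add(doc)
        assert flat.lookup("http://example.org/d/a") is doc.entries["a"]


class TestCheckData:
    def test_valid_double_with_units(self, units_registry):
        stub = build_stub_dictionary(["mass"], "http://example.org/m/", "m")
        entry = stub.entries["mass"]
        entry.data_type = "xsd:double"
        entry.unit_type = "unitType:mass"
        item = scalar_item("180.16", dataType="xsd:double", units="unit:dalton")
        assert check_data(item, entry, units_registry) == []

    def test_non_numeric_double_fails(self, dict_registry):
        entry = dict_registry.lookup("dummy:molecmass")
        issues = check_data(scalar_item("abc"), entry)
        assert "DAT-001" in {i.rule_code for i in issues}

    def test_enumeration_violation(self):
        stub = build_stub_dictionary(["basis"], "http://example.org/e/", "e")
        entry = stub.entries["basis"]
        entry.enumeration = ["6-31G", "cc-pVDZ"]
        issues = check_data(scalar_item("STO-3G"), entry)
        assert {i.rule_code for i in issues} == {"DAT-002"}

    def test_default_units_applied_as_info(self, dict_registry):
        entry = dict_registry.lookup("dummy:molecmass")
        item = scalar_item("180.16")
        issues = check_data(item, entry)
        assert [(i.severity, i.rule_code) for i in issues] == [("info", "DAT-004")]
        assert effective_units(item, entry) == "unit:dalton"

    def test_conflicting_unittype(self, dict_registry, units_registry):
        # entry expects unitType:amount; angstrom carries unitType:length
        entry = dict_registry.lookup("dummy:molecmass")
        item = scalar_item("1.54", units="unit:angstrom")
        issues = check_data(item, entry, units_registry)
        assert {i.rule_code for i in issues} == {"DAT-003"}

    def test_integer_type(self):
        stub = build_stub_dictionary(["nAtoms"], "http://example.org/i/", "i")
        entry = stub.entries["nAtoms"]
        entry.data_type = "xsd:integer"
        assert check_data(scalar_item("42"), entry) == []
        assert {i.rule_code for i in check_data(scalar_item("4.2"), entry)} == {
            "DAT-001"}


class TestHarvest:
    def test_counts_and_resolution(self, dict_registry):
        corpus = generate_compchem_corpus(
            seed=3, n_docs=3, known_terms=["dummy:molecmass"],
            unknown_terms=["cc:weird"])
        records = harvest_terms(corpus.docs, dict_registry)
        assert records["dummy:molecmass"].count == 3
        assert records["dummy:molecmass"].resolved
        if "cc:weird" in records:
            assert not records["cc:weird"].resolved

    def test_empty_corpus(self, dict_registry):
        assert harvest_terms([], dict_registry) == {}

    def test_ordering_and_paths(self, dict_registry):
        corpus = generate_compchem_corpus(
            seed=5, n_docs=4, known_terms=["cc:a", "cc:b"], unknown_terms=[])
        records = harvest_terms(corpus.docs, dict_registry)
        assert list(records) == ["cc:a", "cc:b"]  # equal counts -> lexicographic
        assert len(records["cc:a"].paths) == 3  # capped at 3 examples
        assert records["cc:a"].paths[0].startswith("doc[0]/cml")

    def test_tsv_report_shape(self, dict_registry):
        corpus = generate_compchem_corpus(seed=1, n_docs=2,
                                          known_terms=["cc:hostname"])
        tsv = harvest_report_tsv(harvest_terms(corpus.docs, dict_registry))
        lines = tsv.strip().splitlines()
        assert lines[0] == "qref\tcount\tresolved\texample_path"
        assert lines[1].startswith("cc:hostname\t2\t")


class TestBuildStub:
    def test_action_phrase_dictionary(self, fixtures):
        stub = build_stub_dictionary(
            fixtures.action_phrases,
            "http://www.xml-cml.org/dictionary/synthActions/", "action")
        assert len(stub.entries) == 21
        assert list(stub.entries)[0] == "Add"
        assert list(stub.entries)[-1] == "Yield"
        assert all(e.definition == STUB_DEFINITION for e in stub.entries.values())

    def test_empty_term_list(self):
        stub = build_stub_dictionary([], "http://example.org/x/", "x")
        assert stub.entries == {}
        assert validate(stub.to_cml()).issues == []

    def test_datatype_inference(self):
        stub = build_stub_dictionary(
            ["energy", "method"], "http://example.org/cc/", "cc",
            observed={"energy": ("scalar", ["-76.4", "1e-3"]),
                      "method": ("scalar", ["B3LYP"])})
        assert stub.entries["energy"].data_type == "xsd:double"
        assert stub.entries["method"].data_type == "xsd:string"

    def test_invalid_ncname_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="invalid NCName"):
            stub = build_stub_dictionary(["good", "1bad"],
                                         "http://example.org/x/", "x")
        assert list(stub.entries) == ["good"]

    @given(st.lists(
        st.from_regex(r"[A-Za-z_][A-Za-z0-9_.\-]{0,12}", fullmatch=True),
        max_size=8))
    def test_stub_always_passes_dictionary_rules(self, terms):
        stub = build_stub_dictionary(terms, "http://example.org/rand/", "rnd")
        assert validate(stub.to_cml()).issues == []
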