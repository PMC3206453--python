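# Methods

## The model

The package treats a CML document as an uninterpreted element tree
(`CMLNode`: local name, namespace, text attributes, text content, ordered
children, accumulated `xmlns` bindings) over which three semantic mechanisms
operate:

1. **Convention scoping.** A `convention` attribute opens a scope covering
   its element and all descendants; a nested `convention` attribute
   overrides the outer convention for its subtree. Validation runs the rule
   set registered for each scope's resolved convention URI and emits
   ordered `(severity, rule code, path, message)` issues; a document is
   conformant iff no error-severity issue exists. Elements outside every
   scope contribute nothing — content a processor does not understand is
   transparently ignored, never rejected.
2. **Reference resolution.** Reference attributes (`dictRef`, `units`,
   `unitType`, `convention`, `dataType`) hold QNames. A prefix resolves
   first against the document's in-scope `xmlns` bindings, then against the
   preferred-prefix hints of a local catalog; the namespace URI concatenated
   with the local part is the global identifier, and the mapping is a
   bijection on a fixed catalog. Dereferencing is strictly offline through
   the catalog's namespace→file map.
3. **Units as scaled instances of kinds of quantity.** A unitType carries a
   `Dimension`: rational exponents over the seven SI base quantities
   (length, mass, time, electric current, thermodynamic temperature, amount
   of substance, luminous intensity) plus numerator/denominator multisets of
   free-text annotation tags. Multiplication and division act exponent-wise;
   annotation multisets merge and **never cancel implicitly** (an explicit
   `normalize()` exists for callers who decide tags should cancel). Equality
   requires equal exponents *and* equal annotation multisets, which is what
   makes mg (drug)/kg (animal) and ppm distinct from plain numbers. A unit
   maps its values to the SI-coherent base of its dimension by
   `x_SI = value · factor + offset`; conversion is composition through the
   base and round-trips to ≤ 1e-12 relative error for non-affine units.

## Assumptions and interpretation choices

- **Eldest containing molecule** — the outermost ancestor `molecule` — is
  the scope for atom-id uniqueness and bond-endpoint resolution, so nested
  fragment molecules share one id space.
- Bond `order` is carried as an uninterpreted token: the community itself
  disagrees on bond semantics, and one exemplar document legitimately mixes
  `"1"`, `"2"` and `"S"`. `role` is likewise never validated.
- Unknown conventions produce a warning, not an error: any group may mint
  one, and a validator cannot enumerate them all. Unresolvable convention
  references are errors.
- The entry-for-every-dictRef contract is an error under `--strict` and a
  warning otherwise, so folksonomy-stage corpora can be harvested before a
  dictionary exists.
- The dalton is registered twice — molecular-mass (dimension mass, factor
  (10⁻³ kg/mol)/N_A with N_A = 6.02214179×10²³ mol⁻¹) and molar-mass
  (dimension mass·amount⁻¹, factor equal to gram-per-mole's) — and the
  conversion target's unitType disambiguates. The Avogadro constant is
  pinned to the 2006 CODATA value consistent with the bundled dictionary
  texts; tests comparing against `scipy.constants` therefore allow 1e-5
  relative slack on the dalton and 1e-9 elsewhere.
- Affine offsets (Celsius) are restricted to the pure-temperature dimension
  and affine units cannot take SI prefixes; both restrictions prevent
  ill-defined products. All 20 SI prefixes are supported; `kilo`+`gram`
  yields factor 1, the SI-coherence quirk of the kilogram.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `strict` (CLI `validate`) | off | missing dictionary entries: error vs warning |
| `convention=` (validate) | declared attributes | force one convention URI over the whole document |
| catalog | bundled | prefix hints + namespace→file map; replaceable via `load_catalog` |
| conversion round-trip tolerance | 1e-12 relative | asserted by the property suite, not enforced at runtime |
| `n_atoms`, `nested`, `seed` (generators) | — | synthetic molecule size/shape; one integer seed drives all randomness |

## Synthetic data: what it emulates and what it does not

`generate_molecular` builds molecules with unique ids and bonds over a
random spanning tree — structurally conformant, chemically meaningless
(coordinates are uniform noise; no valence or geometry). The compchem
corpus generator emits parameter lists with known per-term frequencies
(every known term once per document, unknown terms 0–2 times, seeded), so
harvesting can be checked against the generator's own bookkeeping. Passing
these suites shows the *rules and bookkeeping* are correct; it says nothing
about recognising real program output, which varies far more in structure
and vocabulary than these templates.

The single-fault mutation suite applies one targeted transform per rule code
(18 codes: MOL-001..005, DIC-001..005, UTD-001, UND-001..002, CC-001..002,
UNI-001..003) to a conformant base and asserts the mutant fails exactly its
target rule. Faults that necessarily entangle rules (e.g. renaming a bonded
atom triggers both id-duplication and endpoint rules) are expressed as the
minimal single-rule variant (adding an unbonded duplicate atom).

## Numerical and representational choices

- Attribute values stay text in the model; numbers are parsed only in typed
  views, keeping serialization lossless. Token text (`label`, `scalar`
  values) is trimmed on access; XHTML description blocks are preserved
  verbatim. Inter-element tail whitespace is not significant in any
  supported dialect and is dropped; tree equality compares stripped text.
- Document paths use an XPath-like absolute form with 1-based same-name
  sibling indices (`/fragment/molecule[1]/atomArray[1]/atom[3]`).
- Dimension exponents are exact `Fraction`s (half-integer dimensions cost
  nothing to support); conversion arithmetic is double precision.
- Reports are ordered by document position then rule code, making them
  byte-deterministic for identical inputs.
- NCName validation is ASCII (letters, digits, `_ . -`, no leading digit) —
  a deliberate simplification of the full Unicode production.
- Stub-dictionary dataType inference is crude by design (all-numeric →
  `xsd:double`, else `xsd:string`): real typing is a curation decision, not
  a harvesting one.

## Problem sizes

Everything is desk-scale: the exemplar documents are a 17-atom fragment and
a 2-entry dictionary; property suites use 100-reference bijection samples,
5–8-atom synthetic molecules, 6–10-document corpora, and the full pairwise
conversion matrix of the bundled unit set (~30 registrations). The complete
suite runs in well under a minute.

## Known limitations

- No XSD validation of the full CML schema, no chemistry perception, no
  spectral/crystallographic conventions, no HTTP dereferencing or RDF
  export.
- The bundled unit/unitType dictionaries are a small curated set defined by
  this repository (the reference dialect does not print them); the
  `dimension`, `multiplierToSI`/`constantToSI`, `altUnitType` and
  enumeration/pattern encodings are repo-defined extensions documented in
  `docs/formats.md`.
- Mixed content with significant tails (text interleaved between siblings)
  is not round-trip safe; none of the supported dialects uses it.
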