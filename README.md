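# cml-semantics

Offline tooling for the **semantic layer of Chemical Markup Language (CML)**:
convention-based validation, controlled-vocabulary dictionaries addressed by
QName/URI references, and a scientific-units system with conversion and
annotation-aware dimensional analysis.

CML documents carry chemistry in abstract containers — `molecule`, `atom`,
`bond`, `property`, `parameter`, `scalar`/`array`/`matrix`. Their *meaning*
is attached by three mechanisms, all implemented here:

- **Conventions** (`convention="convention:molecular"`): a named,
  URI-identified rule set a sub-community has agreed to. It governs the
  element and its descendants until overridden by a nested declaration, and a
  validator reports exactly where a document deviates. Built-in rule sets
  cover the `dictionary`, `molecular`, `compchem`, `unit-dictionary` and
  `unitType-dictionary` conventions (e.g. an `atomArray` must have at least
  one `atom`; atom ids must be unique within the *eldest containing
  molecule*; every `bond` needs an `atomRefs2` resolving inside that
  molecule).
- **Dictionaries** (`dictRef="dummy:molecmass"`): each reference is a QName
  whose prefix binds to a dictionary namespace URI; `namespace + id` is a
  globally unique identifier, translatable both ways
  (`dummy:molecmass ⇄ http://www.xml-cml.org/dictionary/dummy/molecmass`).
  There must be an entry for every `dictRef`; entries carry term,
  definition, dataType, unitType and default units, which are enforced at
  run time against the data they describe. Hierarchical lookup lets a
  code-specific dictionary defer to a common computational-chemistry one,
  and harvesting/scaffolding tools grow new dictionaries from document
  corpora.
- **Units** (`units="unit:dalton"`): every unit names a *unitType* (the kind
  of quantity) which carries a dimension vector over the seven SI base
  quantities — extended with non-cancelling annotation tags, so
  mg (drug)/kg (animal) or ppm are *not* plain dimensionless numbers.
  Conversion goes through the SI-coherent base,
  `x_SI = value · factor + offset`, and refuses dimension or annotation
  mismatches.

Everything is offline: namespace URIs are identifiers, dereferenced only
through a local catalog mapping them to files.

## Worked example

The classic molecular-mass/molar-mass confusion around the dalton, resolved
by unitType-disambiguated dual registration. With the dalton defined as one
gram-per-mole divided by the Avogadro constant (N_A = 6.02214179×10²³ mol⁻¹):

```console
$ cmlsem convert 1 unit:dalton si:kilogram
1.66053878316e-27 si:kilogram
$ cmlsem convert 1 unit:dalton unit:gramPerMole
1 unit:gramPerMole
```

The first number is the mass reading, 1 Da = (10⁻³ kg/mol)/N_A ≈
1.660538782×10⁻²⁷ kg; the second is the biochemists' molar-mass reading,
1 Da = 1 g/mol exactly. Converting mg (drug)/kg (animal) to a plain
per-mille fails, because the `drug` and `animal` annotations do not cancel:

```console
$ cmlsem convert 1 unit:mgPerKgBodyMass unit:perMille
Error: no dimensionally compatible reading: ...
```

Validating the bundled polymer-fragment document (its `PML-complete`
convention is resolvable but not one of the registered rule sets, hence a
warning, not an error):

```python
from cmlsemantics import read_cml, validate
from cmlsemantics.fixtures import fixture_path

report = validate(read_cml(fixture_path("polymer_fragment.xml")))
print(report)
print("conformant:", report.conformant)
```

```text
WARNING CNV-002  /fragment: unknown convention http://www.xml-cml.org/dictionary/cml/PML-complete: no registered rule set
conformant: True
```

Other entry points: `cmlsem validate` (with `--strict` the
entry-for-every-dictRef contract becomes an error), `cmlsem resolve`
(QName→URI table), `cmlsem check-dict`, `cmlsem harvest` (dictRef tallies as
TSV) and `cmlsem make-dict` (scaffold a stub dictionary from a corpus).

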