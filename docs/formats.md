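# File formats

## Catalog files

Plain text, whitespace-separated, `#` comments. Two record types:

```
prefix <prefix> <namespace-uri>     # preferred prefix for a namespace
map <namespace-uri> <path>          # local file holding that namespace
```

Relative paths resolve against the catalog file's directory; every mapped
path must exist at load time. The default catalog binds the well-known
prefixes (`convention`, `cml`, `dummy`, `compchem`, `unit`, `si`,
`unitType`, `xsd`) and maps the bundled dictionaries.

## Dictionary documents

CML `dictionary` elements in the exemplar dialect: root attributes
`namespace`, `dictionaryPrefix`, `title` and (normally)
`convention="convention:dictionary"`; `entry` children with `id` (NCName,
unique), `term`, a `definition` child (plain-language, whitespace-normalized
on load) and optionally a rich `description`, `dataType`, `unitType` and
default `units`.

Where the dialect leaves an encoding open, this package defines one and
flags it as an extension:

- **Enumerations** — an `enumeration` child holding `value` children:

  ```xml
  <entry id="basis" term="basis set">
    <definition><xhtml:p>Basis set keyword.</xhtml:p></definition>
    <enumeration><value>6-31G</value><value>cc-pVDZ</value></enumeration>
  </entry>
  ```

- **Syntactic templates** — a `pattern` child whose text is a regular
  expression.
- **Stub metadata** — `build_stub_dictionary` records the observed data
  structure in a `dataStructure` attribute (`scalar`/`array`/`matrix`).

## Unit and unitType dictionaries

Same dictionary dialect, under `convention:unit-dictionary` /
`convention:unitType-dictionary`.

unitType entries declare their dimension in a `dimension` attribute:
whitespace-separated `quantity:exponent` tokens over the seven base
quantities (`length`, `mass`, `time`, `electric_current`, `temperature`,
`amount_of_substance`, `luminous_intensity`), exponents as integers or
fractions (`1/2`); `@tag:count` tokens attach non-cancelling annotations
(positive count → numerator, negative → denominator); the empty string is
pure dimensionless.

```xml
<entry id="doseMassRatio" term="dose mass ratio" dimension="@drug:1 @animal:-1">
```

Unit entries declare `unitType`, a positive `multiplierToSI` and optionally
`constantToSI` (affine units, pure temperature only), encoding
`x_SI = value * multiplierToSI + constantToSI`. A dual registration (the
dalton's molecular-mass vs molar-mass readings) adds `altUnitType` and
`altMultiplierToSI` on the same entry.

## Harvest reports

Tab-separated, one header line: `qref  count  resolved  example_path`,
ordered by descending count then reference text; paths are prefixed with
the 0-based document index, e.g. `doc[2]/cml/module[1]/...`.

## Validation reports

Human-readable lines `SEVERITY CODE /path: message`; the JSON form is an
object `{"conformant": bool, "issues": [{severity, rule_code, path,
message}, ...]}` in the same order (document position, then rule code).
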