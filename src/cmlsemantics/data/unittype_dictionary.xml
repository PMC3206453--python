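<?xml version="1.0" encoding="UTF-8"?>
<!-- Curated unitType dictionary shipped with this package (repo-defined, not a
     published reference dictionary).  The `dimension` attribute encoding is
     documented in docs/formats.md: space-separated quantity:exponent tokens over
     the seven SI base quantities, plus non-cancelling @tag annotation tokens. -->
<dictionary xmlns="http://www.xml-cml.org/schema"
    xmlns:convention="http://www.xml-cml.org/convention/"
    xmlns:xhtml="http://www.w3.org/1999/xhtml"
    convention="convention:unitType-dictionary"
    title="unit types (kinds of quantity) with dimension vectors"
    namespace="http://www.xml-cml.org/unit/unitType/"
    dictionaryPrefix="unitType">
  <entry id="dimensionless" term="dimensionless" dimension="">
    <definition><xhtml:p>A pure number: all seven base-quantity exponents are zero and no annotation tags are attached.</xhtml:p></definition>
  </entry>
  <entry id="length" term="length" dimension="length:1">
    <definition><xhtml:p>Spatial extent; SI base quantity with coherent unit metre.</xhtml:p></definition>
  </entry>
  <entry id="mass" term="mass" dimension="mass:1">
    <definition><xhtml:p>Inertial mass; SI base quantity with coherent unit kilogram.</xhtml:p></definition>
  </entry>
  <entry id="time" term="time" dimension="time:1">
    <definition><xhtml:p>Duration; SI base quantity with coherent unit second.</xhtml:p></definition>
  </entry>
  <entry id="electricCurrent" term="electric current" dimension="electric_current:1">
    <definition><xhtml:p>Electric current; SI base quantity with coherent unit ampere.</xhtml:p></definition>
  </entry>
  <entry id="temperature" term="thermodynamic temperature" dimension="temperature:1">
    <definition><xhtml:p>Thermodynamic temperature; SI base quantity with coherent unit kelvin.</xhtml:p></definition>
  </entry>
  <entry id="amount" term="amount of substance" dimension="amount_of_substance:1">
    <definition><xhtml:p>Amount of substance; SI base quantity with coherent unit mole.</xhtml:p></definition>
  </entry>
  <entry id="luminousIntensity" term="luminous intensity" dimension="luminous_intensity:1">
    <definition><xhtml:p>Luminous intensity; SI base quantity with coherent unit candela.</xhtml:p></definition>
  </entry>
  <entry id="molarMass" term="molar mass" dimension="mass:1 amount_of_substance:-1">
    <definition><xhtml:p>Mass per amount of substance; coherent unit kilogram per mole.</xhtml:p></definition>
  </entry>
  <entry id="volume" term="volume" dimension="length:3">
    <definition><xhtml:p>Three-dimensional spatial extent; coherent unit cubic metre.</xhtml:p></definition>
  </entry>
  <entry id="mixingRatio" term="mixing ratio" dimension="@part:1 @whole:-1">
    <definition><xhtml:p>An annotated dimensionless ratio of a part to the whole (e.g. ppm); the part and whole tags do not cancel, so it is distinct from a pure number.</xhtml:p></definition>
  </entry>
  <entry id="doseMassRatio" term="dose mass ratio" dimension="@drug:1 @animal:-1">
    <definition><xhtml:p>Mass of administered drug per body mass of animal (mg (drug)/kg (animal)); the mass exponents cancel but the drug and animal tags do not.</xhtml:p></definition>
  </entry>
  <entry id="biologicalActivityConcentration" term="biological activity concentration" dimension="length:-3 @JurkatUnit:1">
    <definition><xhtml:p>Assay-defined activity units per volume, e.g. Jurkat units per millilitre; the activity tag has no SI dimension of its own.</xhtml:p></definition>
  </entry>
</dictionary>
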