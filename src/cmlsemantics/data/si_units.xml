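<?xml version="1.0" encoding="UTF-8"?>
<!-- Curated SI unit dictionary shipped with this package (repo-defined, not a
     published reference dictionary).  multiplierToSI/constantToSI encode the
     mapping x_SI = value * multiplierToSI + constantToSI; see docs/formats.md. -->
<dictionary xmlns="http://www.xml-cml.org/schema"
    xmlns:convention="http://www.xml-cml.org/convention/"
    xmlns:unitType="http://www.xml-cml.org/unit/unitType/"
    xmlns:xhtml="http://www.w3.org/1999/xhtml"
    convention="convention:unit-dictionary"
    title="SI units"
    namespace="http://www.xml-cml.org/unit/si/"
    dictionaryPrefix="si">
  <entry id="metre" term="metre" unitType="unitType:length" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of length.</xhtml:p></definition>
  </entry>
  <entry id="kilogram" term="kilogram" unitType="unitType:mass" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of mass.</xhtml:p></definition>
  </entry>
  <entry id="second" term="second" unitType="unitType:time" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of time.</xhtml:p></definition>
  </entry>
  <entry id="ampere" term="ampere" unitType="unitType:electricCurrent" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of electric current.</xhtml:p></definition>
  </entry>
  <entry id="kelvin" term="kelvin" unitType="unitType:temperature" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of thermodynamic temperature.</xhtml:p></definition>
  </entry>
  <entry id="mole" term="mole" unitType="unitType:amount" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of amount of substance.</xhtml:p></definition>
  </entry>
  <entry id="candela" term="candela" unitType="unitType:luminousIntensity" multiplierToSI="1">
    <definition><xhtml:p>The SI base unit of luminous intensity.</xhtml:p></definition>
  </entry>
  <entry id="gram" term="gram" unitType="unitType:mass" multiplierToSI="1.0e-3">
    <definition><xhtml:p>One thousandth of a kilogram; the historical CGS mass unit accepted within SI prefixing practice.</xhtml:p></definition>
  </entry>
  <entry id="celsius" term="degree Celsius" unitType="unitType:temperature" multiplierToSI="1" constantToSI="273.15">
    <definition><xhtml:p>Affine temperature unit: T/K = t/degC + 273.15.</xhtml:p></definition>
  </entry>
  <entry id="kilogramPerMole" term="kilogram per mole" unitType="unitType:molarMass" multiplierToSI="1">
    <definition><xhtml:p>The SI coherent unit of molar mass.</xhtml:p></definition>
  </entry>
  <entry id="cubicMetre" term="cubic metre" unitType="unitType:volume" multiplierToSI="1">
    <definition><xhtml:p>The SI coherent unit of volume.</xhtml:p></definition>
  </entry>
</dictionary>
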