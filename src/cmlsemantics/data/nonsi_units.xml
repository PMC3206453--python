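<?xml version="1.0" encoding="UTF-8"?>
<!-- Curated non-SI unit dictionary shipped with this package (repo-defined, not
     a published reference dictionary).  The dalton carries a dual registration
     (molecular-mass and molar-mass readings) via altUnitType/altMultiplierToSI;
     see docs/formats.md.  Its mass multiplier is (1e-3 kg/mol) / N_A with
     N_A = 6.02214179e23 1/mol. -->
<dictionary xmlns="http://www.xml-cml.org/schema"
    xmlns:convention="http://www.xml-cml.org/convention/"
    xmlns:unitType="http://www.xml-cml.org/unit/unitType/"
    xmlns:xhtml="http://www.w3.org/1999/xhtml"
    convention="convention:unit-dictionary"
    title="non-SI units"
    namespace="http://www.xml-cml.org/unit/nonSi/"
    dictionaryPrefix="unit">
  <entry id="dalton" term="dalton" unitType="unitType:mass" multiplierToSI="1.660538783162726e-27"
         altUnitType="unitType:molarMass" altMultiplierToSI="1.0e-3">
    <definition><xhtml:p>Unified atomic mass unit: 1/12 the mass of a carbon-12 atom, equal to one gram per mole divided by the Avogadro constant. In biochemical molar-mass usage 1 Da = 1 g/mol.</xhtml:p></definition>
  </entry>
  <entry id="gramPerMole" term="gram per mole" unitType="unitType:molarMass" multiplierToSI="1.0e-3">
    <definition><xhtml:p>The customary chemistry unit of molar mass.</xhtml:p></definition>
  </entry>
  <entry id="angstrom" term="angstrom" unitType="unitType:length" multiplierToSI="1.0e-10">
    <definition><xhtml:p>10^-10 metre; customary unit for bond lengths and crystallographic cells.</xhtml:p></definition>
  </entry>
  <entry id="litre" term="litre" unitType="unitType:volume" multiplierToSI="1.0e-3">
    <definition><xhtml:p>One cubic decimetre.</xhtml:p></definition>
  </entry>
  <entry id="ppm" term="part per million" unitType="unitType:mixingRatio" multiplierToSI="1.0e-6">
    <definition><xhtml:p>Annotated dimensionless mixing ratio of 10^-6; not interconvertible with a pure number.</xhtml:p></definition>
  </entry>
  <entry id="perMille" term="per mille" unitType="unitType:dimensionless" multiplierToSI="1.0e-3">
    <definition><xhtml:p>A plain dimensionless ratio of 10^-3.</xhtml:p></definition>
  </entry>
  <entry id="mgPerKgBodyMass" term="milligram (drug) per kilogram (animal)" unitType="unitType:doseMassRatio" multiplierToSI="1.0e-6">
    <definition><xhtml:p>Pharmacological dose unit; the drug and animal annotations do not cancel.</xhtml:p></definition>
  </entry>
  <entry id="jurkatUnitPerMillilitre" term="Jurkat unit per millilitre" unitType="unitType:biologicalActivityConcentration" multiplierToSI="1.0e6">
    <definition><xhtml:p>Assay-defined interleukin-2 activity per millilitre of medium.</xhtml:p></definition>
  </entry>
</dictionary>
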