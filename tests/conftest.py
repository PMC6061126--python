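import warnings

import numpy as np
import pytest

from qspreduce.pbpk import build_pbpk, compound_fixture, physiological_fixture

# Gramian rank-deficiency warnings are expected on the PBPK model (one
# balanced direction sits at machine precision); they would otherwise
# drown test output.
warnings.filterwarnings(
    "ignore", message="Gramian product numerically rank deficient")

COMPOUNDS = ["pindolol", "midazolam", "thiopental"]


@pytest.fixture()
def phys():
    return physiological_fixture()


@pytest.fixture(params=COMPOUNDS)
def pbpk_model(request, phys):
    return build_pbpk(phys, compound_fixture(request.param))


@pytest.fixture()
def rng():
    return np.random.default_rng(20180326)


ISO_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="iso">
  <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="1"/>
   <species id="B" compartment="cell" initialConcentration="0"/>
  </listOfSpecies>
  <listOfParameters><parameter id="kf" value="1"/><parameter id="kr" value="2"/></listOfParameters>
  <listOfReactions>
   <reaction id="fwd" reversible="false">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>kf</ci><ci>A</ci></apply>
    </math></kineticLaw>
   </reaction>
   <reaction id="rev" reversible="false">
    <listOfReactants><speciesReference species="B"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>kr</ci><ci>B</ci></apply>
    </math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""

MM_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="mm">
  <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
  <listOfSpecies>
   <species id="S" compartment="cell" initialConcentration="1"/>
   <species id="E" compartment="cell" initialConcentration="0.5"/>
   <species id="C" compartment="cell" initialConcentration="0"/>
   <species id="P" compartment="cell" initialConcentration="0"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k1" value="10"/><parameter id="km1" value="1"/>
   <parameter id="k2" value="2"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="bind" reversible="false">
    <listOfReactants><speciesReference species="S"/><speciesReference species="E"/></listOfReactants>
    <listOfProducts><speciesReference species="C"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k1</ci><ci>S</ci><ci>E</ci></apply>
    </math></kineticLaw>
   </reaction>
   <reaction id="unbind" reversible="false">
    <listOfReactants><speciesReference species="C"/></listOfReactants>
    <listOfProducts><speciesReference species="S"/><speciesReference species="E"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>km1</ci><ci>C</ci></apply>
    </math></kineticLaw>
   </reaction>
   <reaction id="cat" reversible="false">
    <listOfReactants><speciesReference species="C"/></listOfReactants>
    <listOfProducts><speciesReference species="E"/><speciesReference species="P"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k2</ci><ci>C</ci></apply>
    </math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""


@pytest.fixture()
def iso_sbml(tmp_path):
    p = tmp_path / "iso.xml"
    p.write_text(ISO_SBML)
    return p


@pytest.fixture()
def mm_sbml(tmp_path):
    p = tmp_path / "mm.xml"
    p.write_text(MM_SBML)
    return p
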