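"""Minimal SBML Level 3 Version 1 export of the desaturation network.

The writer emits species, parameters, mass-action kinetic laws and the
optional Michaelis-Menten cyclisation branches as MathML rate laws, so the
model can be cross-checked in independent simulators.  Only export is
supported; SBML is never read back.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

from .pathway import KineticParameters, ReactionNetwork

__all__ = ["to_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(name: str) -> str:
    return (
        name.replace("-", "_").replace(":", "_").replace("(", "").replace(")", "")
    )


def _math(expr_ci: list) -> ET.Element:
    """<math><apply><times/><ci>..</ci>...</apply></math> product of factors."""
    math = ET.Element(f"{{{MATHML_NS}}}math")
    apply = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(apply, f"{{{MATHML_NS}}}times")
    for name in expr_ci:
        ci = ET.SubElement(apply, f"{{{MATHML_NS}}}ci")
        ci.text = f" {name} "
    return math


def _mm_math(vmax_id: str, km_id: str, substrate_id: str) -> ET.Element:
    """vmax*S/(km+S) as MathML."""
    math = ET.Element(f"{{{MATHML_NS}}}math")
    div = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(div, f"{{{MATHML_NS}}}divide")
    num = ET.SubElement(div, f"{{{MATHML_NS}}}apply")
    ET.SubElement(num, f"{{{MATHML_NS}}}times")
    for name in (vmax_id, substrate_id):
        ci = ET.SubElement(num, f"{{{MATHML_NS}}}ci")
        ci.text = f" {name} "
    den = ET.SubElement(div, f"{{{MATHML_NS}}}apply")
    ET.SubElement(den, f"{{{MATHML_NS}}}plus")
    for name in (km_id, substrate_id):
        ci = ET.SubElement(den, f"{{{MATHML_NS}}}ci")
        ci.text = f" {name} "
    return math


def _reaction(
    parent: ET.Element,
    rid: str,
    reactants: list[str],
    products: list[str],
    math: ET.Element,
) -> None:
    r = ET.SubElement(
        parent, f"{{{SBML_NS}}}reaction", id=rid, reversible="false", fast="false"
    )
    lor = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
    for s in reactants:
        ET.SubElement(
            lor, f"{{{SBML_NS}}}speciesReference",
            species=s, stoichiometry="1", constant="true",
        )
    lop = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
    for s in products:
        ET.SubElement(
            lop, f"{{{SBML_NS}}}speciesReference",
            species=s, stoichiometry="1", constant="true",
        )
    kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
    kl.append(math)


def to_sbml(
    network: ReactionNetwork,
    params: KineticParameters,
    path: str | Path | None = None,
    model_id: str = "desaturation_network",
) -> str:
    """Serialise the network to an SBML L3V1 string (and optionally a file)."""
    if len(params.k_f) != len(network.species):
        raise ValueError("parameter dimensions do not match the network")
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", level="3", version="1")
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", id=model_id)

    loc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        loc, f"{{{SBML_NS}}}compartment",
        id="assay", spatialDimensions="3", size="1", constant="true",
    )

    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    all_names = (
        network.chain_names
        + network.branch_product_names
        + (network.enzyme,)
        + network.complex_names
    )
    for name in all_names:
        ET.SubElement(
            los, f"{{{SBML_NS}}}species",
            id=_sid(name), name=name, compartment="assay",
            initialConcentration="0", hasOnlySubstanceUnits="false",
            boundaryCondition="false", constant="false",
        )

    lop = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")

    def param(pid: str, value: float) -> None:
        ET.SubElement(
            lop, f"{{{SBML_NS}}}parameter",
            id=pid, value=repr(float(value)), constant="true",
        )

    m = len(network.species)
    for i in range(m):
        param(f"k_f_{i}", params.k_f[i])
        param(f"k_r_{i}", params.k_r[i])
    for i in range(m - 1):
        param(f"k_cat_{i}", params.k_cat[i])
    for k, b in enumerate(network.branches):
        param(f"vmax_{k}", b.vmax)
        param(f"km_{k}", b.km)

    lorx = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    enz = _sid(network.enzyme)
    for i, sp in enumerate(network.species):
        cx = _sid(network.complex_names[i])
        _reaction(
            lorx, f"bind_{i}", [enz, _sid(sp.name)], [cx],
            _math([f"k_f_{i}", enz, _sid(sp.name)]),
        )
        _reaction(lorx, f"unbind_{i}", [cx], [enz, _sid(sp.name)],
                  _math([f"k_r_{i}", cx]))
        if i < m - 1:
            _reaction(
                lorx, f"cat_{i}", [cx], [enz, _sid(network.species[i + 1].name)],
                _math([f"k_cat_{i}", cx]),
            )
    for k, b in enumerate(network.branches):
        _reaction(
            lorx, f"cyclise_{k}", [_sid(b.source)], [_sid(b.product)],
            _mm_math(f"vmax_{k}", f"km_{k}", _sid(b.source)),
        )

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
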