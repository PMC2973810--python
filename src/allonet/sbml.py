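"""Minimal SBML Level 3 (core, version 2) export of compiled networks.

Writes species, compartment and mass-action kinetic laws directly as XML.
Reversible reactions are exported with a two-term kinetic law
(kf * reactants - kb * products); catalytic steps are irreversible.
Species identifiers are sanitized canonical labels, with the original
label preserved in the species ``name`` attribute.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

__all__ = ["network_to_sbml", "write_sbml"]

_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML = "http://www.w3.org/1998/Math/MathML"


def _sid(label: str, taken: dict[str, str]) -> str:
    if label in taken:
        return taken[label]
    base = re.sub(r"[^A-Za-z0-9_]", "_", label)
    if not base or not (base[0].isalpha() or base[0] == "_"):
        base = "s_" + base
    sid = base
    i = 1
    while sid in taken.values():
        i += 1
        sid = f"{base}_{i}"
    taken[label] = sid
    return sid


def _math_product(parent, rate_id, species_ids):
    math = ET.SubElement(parent, f"{{{_MATHML}}}math")
    terms = [rate_id] + list(species_ids)
    if len(terms) == 1:
        ET.SubElement(math, f"{{{_MATHML}}}ci").text = terms[0]
        return
    apply_el = ET.SubElement(math, f"{{{_MATHML}}}apply")
    ET.SubElement(apply_el, f"{{{_MATHML}}}times")
    for t in terms:
        ET.SubElement(apply_el, f"{{{_MATHML}}}ci").text = t


def _math_difference(parent, fwd, back):
    math = ET.SubElement(parent, f"{{{_MATHML}}}math")
    minus = ET.SubElement(math, f"{{{_MATHML}}}apply")
    ET.SubElement(minus, f"{{{_MATHML}}}minus")
    for rate_id, sids in (fwd, back):
        apply_el = ET.SubElement(minus, f"{{{_MATHML}}}apply")
        ET.SubElement(apply_el, f"{{{_MATHML}}}times")
        for t in [rate_id] + list(sids):
            ET.SubElement(apply_el, f"{{{_MATHML}}}ci").text = t


def network_to_sbml(network, initial: dict[str, float] | None = None, model_id: str = "allonet_model") -> str:
    """Serialize a compiled network as an SBML L3 document string."""
    ET.register_namespace("", _NS)
    ET.register_namespace("math", _MATHML)
    sbml = ET.Element(f"{{{_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{_NS}}}model", {"id": model_id})

    compartments = ET.SubElement(model, f"{{{_NS}}}listOfCompartments")
    ET.SubElement(
        compartments,
        f"{{{_NS}}}compartment",
        {"id": "cell", "size": "1", "constant": "true", "spatialDimensions": "3"},
    )

    taken: dict[str, str] = {}
    species_el = ET.SubElement(model, f"{{{_NS}}}listOfSpecies")
    initial = initial or {}
    for lbl in network.species_order():
        ET.SubElement(
            species_el,
            f"{{{_NS}}}species",
            {
                "id": _sid(lbl, taken),
                "name": lbl,
                "compartment": "cell",
                "initialConcentration": repr(float(initial.get(lbl, 0.0))),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    params_el = ET.SubElement(model, f"{{{_NS}}}listOfParameters")
    reactions_el = ET.SubElement(model, f"{{{_NS}}}listOfReactions")
    for n, r in enumerate(network.reactions):
        rid = f"r{n}"
        rev = bool(r.kb)
        rxn = ET.SubElement(
            reactions_el,
            f"{{{_NS}}}reaction",
            {"id": rid, "reversible": "true" if rev else "false", "name": r.provenance},
        )
        lo_re = ET.SubElement(rxn, f"{{{_NS}}}listOfReactants")
        for lbl in r.reactants:
            ET.SubElement(
                lo_re,
                f"{{{_NS}}}speciesReference",
                {"species": taken[lbl], "stoichiometry": "1", "constant": "true"},
            )
        lo_pr = ET.SubElement(rxn, f"{{{_NS}}}listOfProducts")
        for lbl in r.products:
            ET.SubElement(
                lo_pr,
                f"{{{_NS}}}speciesReference",
                {"species": taken[lbl], "stoichiometry": "1", "constant": "true"},
            )
        kf_id = f"kf_{rid}"
        ET.SubElement(
            params_el,
            f"{{{_NS}}}parameter",
            {"id": kf_id, "value": repr(float(r.kf or 0.0)), "constant": "true"},
        )
        law = ET.SubElement(rxn, f"{{{_NS}}}kineticLaw")
        if rev:
            kb_id = f"kb_{rid}"
            ET.SubElement(
                params_el,
                f"{{{_NS}}}parameter",
                {"id": kb_id, "value": repr(float(r.kb)), "constant": "true"},
            )
            _math_difference(
                law,
                (kf_id, [taken[l] for l in r.reactants]),
                (kb_id, [taken[l] for l in r.products]),
            )
        else:
            _math_product(law, kf_id, [taken[l] for l in r.reactants])

    ET.indent(sbml)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(sbml, encoding="unicode")


def write_sbml(network, path, initial=None, model_id="allonet_model") -> None:
    with open(path, "w") as fh:
        fh.write(network_to_sbml(network, initial=initial, model_id=model_id))
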