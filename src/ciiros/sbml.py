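"""Minimal SBML Level 3 export/import for mass-action networks.

The writer emits standard SBML L3 core (compartments, species with
``boundaryCondition`` for clamped species, reactions with MathML kinetic
laws of the form ``kf*prod(reactants) - kr*prod(products)`` and kf/kr as
local parameters).  The reader consumes that subset: it requires every
reaction to carry a kinetic law with a ``kf`` local parameter (and ``kr``
when the reaction is reversible) and reports any construct it cannot map
instead of silently dropping it.  Documents produced by :func:`write_sbml`
round-trip exactly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .network import CLAMPED_PARAM_BY_SPECIES, Network, Reaction, Species
from .params import ParameterSet

__all__ = ["write_sbml", "read_sbml", "SbmlError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ORDER_NS = "https://ciiros.invalid/kinetic-orders"


class SbmlError(ValueError):
    """Malformed document or construct outside the supported subset."""


def _sid(raw: str) -> str:
    return "s_" + raw


def _rid(raw: str) -> str:
    return "r_" + raw


def _math_product(parent: ET.Element, k: str, terms: list[tuple[str, int]]) -> None:
    if not terms:
        ET.SubElement(parent, f"{{{MATHML_NS}}}ci").text = k
        return
    times = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
    ET.SubElement(times, f"{{{MATHML_NS}}}times")
    ET.SubElement(times, f"{{{MATHML_NS}}}ci").text = k
    for sid, order in terms:
        if order == 1:
            ET.SubElement(times, f"{{{MATHML_NS}}}ci").text = _sid(sid)
        else:
            power = ET.SubElement(times, f"{{{MATHML_NS}}}apply")
            ET.SubElement(power, f"{{{MATHML_NS}}}power")
            ET.SubElement(power, f"{{{MATHML_NS}}}ci").text = _sid(sid)
            cn = ET.SubElement(power, f"{{{MATHML_NS}}}cn")
            cn.set("type", "integer")
            cn.text = str(order)


def write_sbml(network: Network, params: ParameterSet, path) -> None:
    """Serialise the network (with resolved rate constants) to SBML L3."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          {"id": "complex_ii_ros", "substanceUnits": "mole",
                           "timeUnits": "second", "extentUnits": "mole"})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid in sorted({s.compartment for s in network.species}):
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                      {"id": cid.replace("-", "_"), "constant": "true",
                       "size": "1", "spatialDimensions": "3"})
    x0 = network.initial_state(params)
    sp_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in network.species:
        conc = params[CLAMPED_PARAM_BY_SPECIES[s.id]] \
            if s.clamped and s.id in CLAMPED_PARAM_BY_SPECIES \
            else (s.concentration if s.clamped else float(x0[network.free_index(s.id)]))
        attrs = {
            "id": _sid(s.id),
            "name": s.description or s.id,
            "compartment": s.compartment.replace("-", "_"),
            "initialConcentration": repr(float(conc)),
            "boundaryCondition": "true" if s.clamped else "false",
            "constant": "false",
            "hasOnlySubstanceUnits": "false",
        }
        ET.SubElement(sp_el, f"{{{SBML_NS}}}species", attrs)
    rx_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        kf, kr = r.constants(params)
        rel = ET.SubElement(rx_el, f"{{{SBML_NS}}}reaction",
                            {"id": _rid(r.rid), "name": r.description or r.rid,
                             "reversible": "true" if r.reversible else "false"})
        if r.reactants:
            lst = ET.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
            for sid, n in r.reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": _sid(sid), "stoichiometry": str(n),
                               "constant": "true"})
        if r.products:
            lst = ET.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
            for sid, n in r.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": _sid(sid), "stoichiometry": str(n),
                               "constant": "true"})
        kl = ET.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
        # annotation keeps non-stoichiometric kinetic orders machine-readable
        if r.fwd_orders is not None or r.rev_orders is not None:
            ann = ET.SubElement(kl, f"{{{SBML_NS}}}annotation")
            orders = ET.SubElement(ann, f"{{{_ORDER_NS}}}orders")
            if r.fwd_orders is not None:
                orders.set("forward", ";".join(f"{s}:{n}" for s, n in r.fwd_orders))
            if r.rev_orders is not None:
                orders.set("reverse", ";".join(f"{s}:{n}" for s, n in r.rev_orders))
        math = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        fwd = list(r.fwd_orders if r.fwd_orders is not None else r.reactants)
        rev = list(r.rev_orders if r.rev_orders is not None else r.products)
        if r.reversible:
            minus = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
            ET.SubElement(minus, f"{{{MATHML_NS}}}minus")
            _math_product(minus, "kf", fwd)
            _math_product(minus, "kr", rev)
        else:
            _math_product(math, "kf", fwd)
        lop = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        ET.SubElement(lop, f"{{{SBML_NS}}}localParameter",
                      {"id": "kf", "value": repr(float(kf))})
        if r.reversible:
            ET.SubElement(lop, f"{{{SBML_NS}}}localParameter",
                          {"id": "kr", "value": repr(float(kr))})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def _parse_orders(kl: ET.Element, attr: str) -> tuple[tuple[str, int], ...] | None:
    orders = kl.find(f"{{{SBML_NS}}}annotation/{{{_ORDER_NS}}}orders")
    if orders is None or attr not in orders.attrib:
        return None
    raw = orders.get(attr)
    if not raw:
        return ()
    return tuple((p.split(":")[0], int(p.split(":")[1])) for p in raw.split(";"))


def read_sbml(path) -> tuple[Network, ParameterSet]:
    """Parse an SBML L3 (or L2) document of the supported mass-action subset."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlError(f"malformed XML in {path.name}: {exc}") from None
    root = tree.getroot()
    if not root.tag.endswith("sbml"):
        raise SbmlError("document root is not an <sbml> element")
    ns = root.tag[1:].split("}")[0]
    level = root.get("level")
    if level not in ("2", "3"):
        raise SbmlError(f"unsupported SBML level {level!r}")

    def q(tag: str) -> str:
        return f"{{{ns}}}{tag}"

    model = root.find(q("model"))
    if model is None:
        raise SbmlError("document has no <model>")

    species: list[Species] = []
    for el in model.iter(q("species")):
        raw = el.get("id", "")
        sid = raw[2:] if raw.startswith("s_") else raw
        comp = (el.get("compartment") or "matrix").replace("_", "-")
        species.append(Species(
            sid, el.get("name", ""), comp,
            el.get("boundaryCondition") == "true",
            float(el.get("initialConcentration") or 0.0),
        ))

    reactions: list[Reaction] = []
    overrides: dict[str, float] = {}
    for s in species:
        if s.clamped and s.id in CLAMPED_PARAM_BY_SPECIES:
            overrides[CLAMPED_PARAM_BY_SPECIES[s.id]] = s.concentration

    def refs(el: ET.Element, tag: str) -> tuple[tuple[str, int], ...]:
        lst = el.find(q(tag))
        if lst is None:
            return ()
        out = []
        for ref in lst.findall(q("speciesReference")):
            raw = ref.get("species", "")
            sid = raw[2:] if raw.startswith("s_") else raw
            out.append((sid, int(float(ref.get("stoichiometry", "1")))))
        return tuple(out)

    for el in model.iter(q("reaction")):
        raw = el.get("id", "")
        rid = raw[2:] if raw.startswith("r_") else raw
        reversible = el.get("reversible", "true") == "true"
        kl = el.find(q("kineticLaw"))
        if kl is None:
            raise SbmlError(f"reaction {rid!r} has no kinetic law")
        local: dict[str, float] = {}
        for lp in kl.iter():
            if lp.tag in (q("localParameter"), q("parameter")) and lp.get("id"):
                local[lp.get("id")] = float(lp.get("value", "nan"))
        if "kf" not in local:
            raise SbmlError(
                f"reaction {rid!r}: unsupported rate law (no 'kf' local parameter; "
                "only mass-action laws written by this package are supported)"
            )
        if reversible and "kr" not in local:
            raise SbmlError(f"reaction {rid!r}: reversible law without 'kr'")
        reactions.append(Reaction(
            rid, refs(el, "listOfReactants"), refs(el, "listOfProducts"),
            "binding" if reversible else "irreversible",
            fwd_orders=_parse_orders(kl, "forward"),
            rev_orders=_parse_orders(kl, "reverse"),
            description=el.get("name", ""),
        ))
        overrides[f"kf{rid}"] = local["kf"]
        if reversible:
            if local["kr"] <= 0:
                raise SbmlError(f"reaction {rid!r}: kr must be positive")
            overrides[f"kr{rid}"] = local["kr"]

    if not reactions:
        raise SbmlError("model contains no reactions")
    params = ParameterSet(**overrides)
    return Network(species, reactions, topology="custom"), params
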