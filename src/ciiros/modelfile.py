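"""YAML/JSON model exchange.

A model document lists species (id, compartment, initial concentration,
clamped flag), reactions (id, reactants, products, reversibility, resolved
kf/kr and optional kinetic orders) and the boundary/total parameters.  Rate
constants are written resolved (electron-transfer reverse constants are
evaluated from the midpoint potentials at export time), so a round trip
preserves every constant to full precision while staying independent of the
thermodynamic bookkeeping of the source network.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .network import (CLAMPED_PARAM_BY_SPECIES, Network, Reaction, Species)
from .params import ParameterSet

__all__ = ["network_to_dict", "network_from_dict", "write_model", "read_model"]


def network_to_dict(network: Network, params: ParameterSet) -> dict:
    x0 = network.initial_state(params)
    species = []
    for s in network.species:
        conc = params[CLAMPED_PARAM_BY_SPECIES.get(s.id, s.id)] if s.clamped \
            else float(x0[network.free_index(s.id)])
        species.append({
            "id": s.id, "description": s.description,
            "compartment": s.compartment, "concentration": conc,
            "clamped": s.clamped,
        })
    reactions = []
    for r in network.reactions:
        kf, kr = r.constants(params)
        entry = {
            "rid": r.rid,
            "reactants": [[sid, n] for sid, n in r.reactants],
            "products": [[sid, n] for sid, n in r.products],
            "reversible": r.reversible,
            "kf": float(kf),
            "kr": float(kr),
            "description": r.description,
        }
        if r.fwd_orders is not None:
            entry["fwd_orders"] = [[sid, n] for sid, n in r.fwd_orders]
        if r.rev_orders is not None:
            entry["rev_orders"] = [[sid, n] for sid, n in r.rev_orders]
        reactions.append(entry)
    return {"topology": network.topology, "species": species,
            "reactions": reactions}


def network_from_dict(doc: dict) -> tuple[Network, ParameterSet]:
    species = []
    overrides: dict[str, float] = {}
    for s in doc["species"]:
        species.append(Species(s["id"], s.get("description", ""),
                               s.get("compartment", "matrix"),
                               bool(s.get("clamped", False)),
                               float(s.get("concentration", 0.0))))
        if s.get("clamped") and s["id"] in CLAMPED_PARAM_BY_SPECIES:
            overrides[CLAMPED_PARAM_BY_SPECIES[s["id"]]] = float(s["concentration"])
    reactions = []
    for r in doc["reactions"]:
        rid = str(r["rid"])
        kind = "binding" if r.get("reversible", True) else "irreversible"
        reactions.append(Reaction(
            rid,
            tuple((sid, int(n)) for sid, n in r["reactants"]),
            tuple((sid, int(n)) for sid, n in r["products"]),
            kind,
            fwd_orders=tuple((sid, int(n)) for sid, n in r["fwd_orders"])
            if "fwd_orders" in r else None,
            rev_orders=tuple((sid, int(n)) for sid, n in r["rev_orders"])
            if "rev_orders" in r else None,
            description=r.get("description", ""),
        ))
        overrides[f"kf{rid}"] = float(r["kf"])
        if kind == "binding":
            kr = float(r["kr"])
            if kr <= 0:
                raise ValueError(f"reversible reaction {rid} needs kr > 0")
            overrides[f"kr{rid}"] = kr
    params = ParameterSet(**overrides)
    return Network(species, reactions, topology=doc.get("topology", "custom")), params


def write_model(network: Network, params: ParameterSet, path) -> None:
    path = Path(path)
    doc = network_to_dict(network, params)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path) -> tuple[Network, ParameterSet]:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_from_dict(doc)
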