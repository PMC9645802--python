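"""JSON (de)serialization of model declarations and run configurations.

The on-disk document has three top-level keys:

* ``model`` — species, compartments, patches, membranes (the declaration);
* ``mesh`` — either ``{"path": "file.msh", "unit_scale": 1.0}`` or
  ``{"generate": {"shape": "cable", "dimensions": [...], "resolution": ...}}``;
* ``run`` — t_end, efield_dt, alpha_rd, seed, ranks, record_dt, probes
  (name -> [x, y, z]), injections ([{"at": [x,y,z] or "z_min", "amps": ...}]).

Rate functions are declared as named built-ins, constants or V->rate tables;
arbitrary code is never read from a config file.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import (Channel, ChannelCurrent, Compartment, DiffusionRule,
                    GhkFlux, Membrane, Model, Patch, RateSpec, Reaction,
                    Species, SurfaceReaction)


def ratespec_to_dict(r: RateSpec) -> dict:
    if r.kind == "const":
        return {"kind": "const", "value": r.value}
    if r.kind == "builtin":
        return {"kind": "builtin", "name": r.name}
    return {"kind": "table", "v_mV": list(r.v_mV), "rate": list(r.rate)}


def ratespec_from_dict(d: dict) -> RateSpec:
    return RateSpec(kind=d["kind"], value=d.get("value", 0.0),
                    name=d.get("name", ""), v_mV=tuple(d.get("v_mV", ())),
                    rate=tuple(d.get("rate", ())))


def model_to_dict(model: Model) -> dict:
    return {
        "species": [{"name": s.name, "valence": s.valence} for s in model.species],
        "compartments": [{
            "name": c.name,
            "reactions": [{"lhs": r.lhs, "rhs": r.rhs, "k": r.k, "units": r.units}
                          for r in c.reactions],
            "diffusion": [{"species": d.species, "D": d.D} for d in c.diffusion],
            "initial": c.initial,
        } for c in model.compartments],
        "patches": [{
            "name": p.name,
            "comp": p.comp,
            "surface_reactions": [{
                "lhs_vol": s.lhs_vol, "lhs_surf": s.lhs_surf,
                "rhs_vol": s.rhs_vol, "rhs_surf": s.rhs_surf,
                "k": s.k, "units": s.units,
            } for s in p.surface_reactions],
            "channels": [{
                "name": ch.name, "states": ch.states,
                "transitions": [[src, dst, mult, ratespec_to_dict(fn)]
                                for src, dst, mult, fn in ch.transitions],
                "currents": [{
                    "state": cur.state, "kind": cur.kind,
                    "g_single": cur.g_single, "erev": cur.erev,
                    "permeability": cur.permeability, "ion": cur.ion,
                    "c_out": cur.c_out,
                } for cur in ch.currents],
                "init": ch.init,
                "density": density,
            } for ch, density in p.channels],
            "ghk_fluxes": [{"ion": g.ion, "permeability": g.permeability,
                            "c_out": g.c_out, "valence": g.valence}
                           for g in p.ghk_fluxes],
            "initial_surf": p.initial_surf,
        } for p in model.patches],
        "membranes": [{
            "patch": m.patch, "capacitance": m.capacitance, "leak_g": m.leak_g,
            "leak_erev": m.leak_erev, "resistivity": m.resistivity,
        } for m in model.membranes],
    }


def model_from_dict(doc: dict) -> Model:
    species = [Species(s["name"], s.get("valence", 0)) for s in doc.get("species", [])]
    comps = []
    for c in doc.get("compartments", []):
        comps.append(Compartment(
            name=c["name"],
            reactions=[Reaction(r["lhs"], r["rhs"], r["k"], r.get("units", "1/s"))
                       for r in c.get("reactions", [])],
            diffusion=[DiffusionRule(d["species"], d["D"])
                       for d in c.get("diffusion", [])],
            initial={k: int(v) for k, v in c.get("initial", {}).items()},
        ))
    patches = []
    for p in doc.get("patches", []):
        chans = []
        for ch in p.get("channels", []):
            chans.append((Channel(
                name=ch["name"], states=list(ch["states"]),
                transitions=[(src, dst, mult, ratespec_from_dict(fn))
                             for src, dst, mult, fn in ch["transitions"]],
                currents=[ChannelCurrent(**cur) for cur in ch.get("currents", [])],
                init=ch.get("init", "stationary"),
            ), float(ch["density"])))
        patches.append(Patch(
            name=p["name"], comp=p["comp"],
            surface_reactions=[SurfaceReaction(
                lhs_vol=s.get("lhs_vol", {}), lhs_surf=s.get("lhs_surf", {}),
                rhs_vol=s.get("rhs_vol", {}), rhs_surf=s.get("rhs_surf", {}),
                k=s["k"], units=s.get("units", "1/s"),
            ) for s in p.get("surface_reactions", [])],
            channels=chans,
            ghk_fluxes=[GhkFlux(**g) for g in p.get("ghk_fluxes", [])],
            initial_surf={k: int(v) for k, v in p.get("initial_surf", {}).items()},
        ))
    membranes = [Membrane(**m) for m in doc.get("membranes", [])]
    return Model(species=species, compartments=comps, patches=patches,
                 membranes=membranes)


def load_config(path) -> dict:
    doc = json.loads(Path(path).read_text())
    for key in ("model",):
        if key not in doc:
            raise ValueError(f"config {path}: missing required key {key!r}")
    return doc


def save_config(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
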