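"""Programmatic builders of the benchmark models.

* ``simple_model_fixture`` — ten diffusing species A..J coupled by four
  reversible bimolecular reactions on a cuboid mesh, with a count-scaling
  series 0.01x .. 100x.
* ``rallpack1_fixture`` — the passive sealed-cable benchmark: leaky membrane,
  step current injection at one end, voltage taps at both ends.
* ``rallpack3_fixture`` — the same cable with stochastic Hodgkin-Huxley Na/K
  channels; channel densities are the classic macroscopic conductances
  (1200 S/m^2 Na, 360 S/m^2 K) divided by the chosen single-channel
  conductance.
* ``two_tet_toy_fixture`` — two face-sharing tetrahedrons with a three-species
  cycle in each, plus surface transfer and a stochastic GHK crossing on one
  triangle of tet 0; exercises surface reactions, GHK flux and the
  dependency-graph decomposition (components of sizes 7 and 3).

Fixtures are pure data: building twice yields identical declarations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efield import hh_gating_model
from .geometry import TetMesh, generate_box, generate_cable
from .model import (Compartment, DiffusionRule, GhkFlux, Membrane, Model,
                    Patch, Reaction, Species, SurfaceReaction)

SIMPLE_SPECIES = "ABCDEFGHIJ"
SIMPLE_D_UM2_S = [100, 90, 80, 70, 60, 50, 40, 30, 20, 10]
SIMPLE_COUNTS = [1000 * (i + 1) for i in range(10)]
SIMPLE_REACTIONS = [  # (reactants, product, kf 1/(uM s), kb 1/s)
    (("A", "B"), "C", 1000.0, 100.0),
    (("C", "D"), "E", 100.0, 10.0),
    (("F", "G"), "H", 10.0, 1.0),
    (("H", "I"), "J", 1.0, 1.0),
]
SIMPLE_SCALES = (0.01, 0.1, 1.0, 10.0, 100.0)


def simple_model_fixture(scale: float = 1.0, mesh_cells: int = 13):
    """(model, mesh) for the ten-species benchmark at a count scale.

    The default mesh is a 13x13x13 µm cube at 1 µm cells (6 tets each,
    13,182 tetrahedrons — the benchmark's cuboid resolution to within ~1%).
    """
    if scale not in SIMPLE_SCALES:
        raise ValueError(f"scale must be one of {SIMPLE_SCALES}")
    species = [Species(s) for s in SIMPLE_SPECIES]
    reactions = []
    for (ra, rb), prod, kf, kb in SIMPLE_REACTIONS:
        reactions.append(Reaction({ra: 1, rb: 1}, {prod: 1}, kf, "1/(uM*s)"))
        reactions.append(Reaction({prod: 1}, {ra: 1, rb: 1}, kb, "1/s"))
    comp = Compartment(
        name="comp",
        reactions=reactions,
        diffusion=[DiffusionRule(s, d * 1e-12)
                   for s, d in zip(SIMPLE_SPECIES, SIMPLE_D_UM2_S)],
        initial={s: int(round(c * scale))
                 for s, c in zip(SIMPLE_SPECIES, SIMPLE_COUNTS)},
    )
    model = Model(species=species, compartments=[comp])
    side = mesh_cells * 1e-6
    mesh = generate_box((side, side, side), (mesh_cells,) * 3,
                        comp="comp", patch=None)
    return model, mesh


@dataclass(frozen=True)
class CableParams:
    """Passive-cable benchmark parameters (SI units)."""

    leak_g: float = 0.25        # S/m^2
    leak_erev: float = -0.065   # V
    resistivity: float = 1.0    # Ohm*m (axial)
    current: float = 0.1e-9     # A, injected at z_min
    length: float = 1.0e-3      # m
    cm: float = 0.01            # F/m^2
    efield_dt: float = 5.0e-6   # s
    diameter: float = 1.0e-6    # m (cable-standard nominal diameter)


def rallpack1_fixture(axial_segments: int = 200, params: CableParams | None = None):
    """(model, mesh, params) for the passive sealed-cable benchmark.

    A leak is present on every surface triangle (lateral and end caps); the
    cable generator's surface-ratio correction makes the per-length membrane
    conductance and capacitance match the ideal cylinder.  Voltage probes
    belong at (0, 0, 0) and (0, 0, L); injection at the z=0 end vertices.
    """
    if axial_segments < 10:
        raise ValueError("use at least 10 axial segments")
    p = params or CableParams()
    mesh = generate_cable(p.length, p.diameter, axial_segments,
                          comp="cyto", patch="memb")
    model = Model(
        species=[],
        compartments=[Compartment(name="cyto")],
        patches=[Patch(name="memb", comp="cyto")],
        membranes=[Membrane(patch="memb", capacitance=p.cm, leak_g=p.leak_g,
                            leak_erev=p.leak_erev, resistivity=p.resistivity)],
    )
    return model, mesh, p


HH_NA_DENSITY = 1200.0  # S/m^2 macroscopic sodium conductance
HH_K_DENSITY = 360.0    # S/m^2 macroscopic potassium conductance
HH_E_NA = 0.050         # V
HH_E_K = -0.077         # V


def rallpack3_fixture(g_single: float = 4e-12, axial_segments: int = 200,
                      params: CableParams | None = None):
    """Rallpack 1 plus stochastic HH Na/K channels at ``g_single`` each.

    Channel densities are the macroscopic conductances divided by the
    single-channel conductance, so a smaller g_single means more, noisier
    channels at the same total conductance.  The benchmark span is 250 ms.
    """
    if g_single <= 0:
        raise ValueError("single-channel conductance must be positive")
    model, mesh, p = rallpack1_fixture(axial_segments, params)
    na, kch = hh_gating_model(g_single_na=g_single, g_single_k=g_single,
                              e_na=HH_E_NA, e_k=HH_E_K)
    patch = model.patches[0]
    patch.channels = [(na, HH_NA_DENSITY / g_single),
                      (kch, HH_K_DENSITY / g_single)]
    return model, mesh, p


def two_tet_mesh() -> TetMesh:
    """Two face-sharing unit-scale tetrahedrons, one tagged boundary triangle."""
    s = 1e-6
    verts = np.array([
        [0, 0, 0], [s, 0, 0], [0, s, 0], [0, 0, s], [s, s, s],
    ], dtype=float)
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]], dtype=np.int64)
    tris = np.array([[0, 1, 2]], dtype=np.int64)  # boundary face of tet 0
    return TetMesh(verts, tets, np.zeros(2, np.int64), ["comp"],
                   tris, np.zeros(1, np.int64), ["memb"])


def two_tet_toy_fixture(rate: float = 1.0, permeability: float = 1e-24,
                        c_out: float = 1.0, ghk_on: bool = True,
                        initial: int = 100):
    """(model, mesh) for the two-tetrahedron surface/GHK exercise.

    Both tets carry the cycle A->B->C->A; tet 0's tagged triangle adds the
    surface transfer C(tet) <-> C(tri) and, when ``ghk_on``, a stochastic GHK
    crossing of C (the outside is not modeled, so crossings create/remove C).
    All rates default to 1/s — the fixture exercises code paths, it
    reproduces no published numbers.
    """
    mesh = two_tet_mesh()
    species = [Species("A"), Species("B"), Species("C", valence=1)]
    cyc = [Reaction({"A": 1}, {"B": 1}, rate),
           Reaction({"B": 1}, {"C": 1}, rate),
           Reaction({"C": 1}, {"A": 1}, rate)]
    patch = Patch(
        name="memb", comp="comp",
        surface_reactions=[
            SurfaceReaction(lhs_vol={"C": 1}, rhs_surf={"C": 1}, k=rate),
            SurfaceReaction(lhs_surf={"C": 1}, rhs_vol={"C": 1}, k=rate),
        ],
        ghk_fluxes=[GhkFlux(ion="C", permeability=permeability,
                            c_out=c_out, valence=1)] if ghk_on else [],
    )
    comp = Compartment(name="comp", reactions=cyc,
                       initial={"A": initial, "B": initial, "C": initial})
    membranes = [Membrane(patch="memb", capacitance=0.01, leak_g=0.25,
                          leak_erev=-0.065)] if ghk_on else []
    model = Model(species=species, compartments=[comp], patches=[patch],
                  membranes=membranes)
    return model, mesh
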