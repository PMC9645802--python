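"""Biochemical model declaration and binding to a tagged mesh.

A :class:`Model` declares species, volume reactions, diffusion rules, surface
reactions, voltage-gated channels and passive membrane parameters, attached to
compartment/patch names that must match the mesh's physical tags.
:func:`bind_model` resolves the declaration against a concrete mesh and
enumerates every kinetic process (one per reaction per element), converting
declared rate constants to per-event propensity coefficients and channel
densities to integer per-triangle channel counts.

Rate-constant units follow the common biochemistry conventions: first order in
``1/s``; second order in ``1/(M*s)`` or ``1/(uM*s)``.  The per-event
coefficient of a bimolecular reaction in a voxel of volume V is
``c = k_SI / (N_A * V_litres)``; for identical reactants the n(n-1)/2
combination count lives in the propensity, not in ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MeshMeasures, TetMesh, compute_measures
from .ssa import KineticProcess

N_AVOGADRO = 6.02214076e23

_RATE_UNIT_TO_SI = {  # multiplicative factor to 1/s (order 1) or 1/(M s) (order 2)
    "1/s": 1.0,
    "1/(M*s)": 1.0,
    "1/(uM*s)": 1.0e6,
}


def stochastic_rate_constant(k: float, units: str, order: int, volume: float | None = None) -> float:
    """Per-event propensity coefficient c (s^-1 per reactant combination)."""
    if units not in _RATE_UNIT_TO_SI:
        raise ValueError(f"unknown rate units {units!r}; expected one of {list(_RATE_UNIT_TO_SI)}")
    if order == 1:
        if units != "1/s":
            raise ValueError("first-order rate constants must be in 1/s")
        return float(k)
    if order == 2:
        if units == "1/s":
            raise ValueError("second-order rate constants need concentration units")
        if volume is None or volume <= 0:
            raise ValueError("second-order conversion requires a positive volume")
        k_si = float(k) * _RATE_UNIT_TO_SI[units]  # 1/(M s)
        return k_si / (N_AVOGADRO * volume * 1.0e3)  # volume m^3 -> litres
    raise ValueError(f"reactions of order {order} are not supported (max 2)")


# ---------------------------------------------------------------------------
# declarations

@dataclass(frozen=True)
class Species:
    name: str
    valence: int = 0  # ionic charge, used by GHK currents


@dataclass
class Reaction:
    """Unidirectional volume reaction; lhs/rhs map species name -> count."""

    lhs: dict[str, int]
    rhs: dict[str, int]
    k: float
    units: str = "1/s"

    @property
    def order(self) -> int:
        return sum(self.lhs.values())


@dataclass
class DiffusionRule:
    species: str
    D: float  # m^2/s

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass
class SurfaceReaction:
    """Unidirectional reaction linking a patch triangle and its inner tet.

    ``*_vol`` stoichiometries live in the adjacent tetrahedron, ``*_surf`` on
    the triangle.  Order-2 coefficients use the tetrahedron volume.
    """

    lhs_vol: dict[str, int] = field(default_factory=dict)
    lhs_surf: dict[str, int] = field(default_factory=dict)
    rhs_vol: dict[str, int] = field(default_factory=dict)
    rhs_surf: dict[str, int] = field(default_factory=dict)
    k: float = 1.0
    units: str = "1/s"

    @property
    def order(self) -> int:
        return sum(self.lhs_vol.values()) + sum(self.lhs_surf.values())


@dataclass
class GhkFlux:
    """Stochastic GHK ion flux across a patch (ion moves one at a time).

    ``permeability`` is the total patch permeability per triangle area
    (m^3/s per m^2 = m/s) unless ``per_triangle`` totals are given at bind
    time by channels; the toy fixture uses a plain per-triangle permeability.
    The external concentration is fixed; the internal one is the inner tet's
    ``count/(N_A * volume)``.
    """

    ion: str
    permeability: float   # m^3/s per triangle
    c_out: float          # mol/m^3
    valence: int = 1


@dataclass
class RateSpec:
    """Voltage-dependent rate: named built-in, constant, or V->rate table."""

    kind: str                   # "const" | "builtin" | "table"
    value: float = 0.0
    name: str = ""
    v_mV: tuple = ()
    rate: tuple = ()

    def __call__(self, v_mV):
        if self.kind == "const":
            return np.full_like(np.asarray(v_mV, dtype=float), self.value)
        if self.kind == "builtin":
            from . import ratefns

            return ratefns.BUILTINS[self.name](np.asarray(v_mV, dtype=float))
        if self.kind == "table":
            return np.interp(np.asarray(v_mV, dtype=float), self.v_mV, self.rate)
        raise ValueError(f"unknown rate kind {self.kind!r}")


@dataclass
class ChannelCurrent:
    """Current carried by one conducting channel state."""

    state: str
    kind: str                 # "ohmic" | "ghk"
    g_single: float = 0.0     # S per open channel (ohmic)
    erev: float = 0.0         # V (ohmic)
    permeability: float = 0.0  # m^3/s per open channel (ghk)
    ion: str = ""             # ghk: species carrying the charge
    c_out: float = 0.0        # mol/m^3 (ghk, fixed outer bath)


@dataclass
class Channel:
    """Multi-state stochastic channel with voltage-dependent transitions."""

    name: str
    states: list[str]
    transitions: list[tuple[str, str, float, RateSpec]]  # (src, dst, multiplicity, rate)
    currents: list[ChannelCurrent] = field(default_factory=list)
    init: str = "stationary"  # or a state name: all channels start there

    def __post_init__(self):
        for src, dst, _, _ in self.transitions:
            if src not in self.states or dst not in self.states:
                raise ValueError(f"transition {src}->{dst} references undeclared state")

    def state_name(self, s: str) -> str:
        return f"{self.name}.{s}"

    def rate_matrix(self, v_mV: float) -> np.ndarray:
        """Generator matrix Q (s^-1) of the state chain at fixed voltage."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for src, dst, mult, fn in self.transitions:
            r = mult * float(fn(v_mV))
            Q[idx[src], idx[dst]] += r
            Q[idx[src], idx[src]] -= r
        return Q

    def stationary(self, v_mV: float) -> np.ndarray:
        """Stationary distribution of the chain at fixed voltage."""
        Q = self.rate_matrix(v_mV)
        n = len(self.states)
        A = np.vstack([Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass
class Compartment:
    name: str
    reactions: list[Reaction] = field(default_factory=list)
    diffusion: list[DiffusionRule] = field(default_factory=list)
    initial: dict[str, int] = field(default_factory=dict)  # total counts


@dataclass
class Patch:
    name: str
    comp: str                  # inner compartment the surface chemistry talks to
    surface_reactions: list[SurfaceReaction] = field(default_factory=list)
    channels: list[tuple[Channel, float]] = field(default_factory=list)  # (chan, density /m^2)
    ghk_fluxes: list[GhkFlux] = field(default_factory=list)
    initial_surf: dict[str, int] = field(default_factory=dict)


@dataclass
class Membrane:
    """Passive electrical properties of a patch."""

    patch: str
    capacitance: float        # F/m^2
    leak_g: float = 0.0       # S/m^2
    leak_erev: float = 0.0    # V
    resistivity: float = 1.0  # Ohm*m, intracellular volume conduction


@dataclass
class Model:
    species: list[Species] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    patches: list[Patch] = field(default_factory=list)
    membranes: list[Membrane] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}


# ---------------------------------------------------------------------------
# bound model

@dataclass
class BoundModel:
    """A model resolved against a tagged mesh: the kinetic-process catalogue."""

    model: Model
    mesh: TetMesh
    measures: MeshMeasures
    vol_species: list[str]            # M columns (per tet)
    surf_species: list[str]           # M_surf columns (per tri), incl. channel states
    processes: list[KineticProcess]
    diffusion: list[tuple[int, float, np.ndarray]]  # (vol species idx, D, tet ids)
    channel_counts: dict[tuple[int, str], np.ndarray]  # (patch tag, channel) -> per-tri totals
    membranes: list[Membrane]

    @property
    def num_processes(self) -> int:
        return len(self.processes)

    def vol_index(self, name: str) -> int:
        return self.vol_species.index(name)

    def surf_index(self, name: str) -> int:
        return self.surf_species.index(name)


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the quotas then hands remaining units to the largest remainders
    (ties to the lower index); the result sums to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    rem = total - int(base.sum())
    if rem:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _check_species(model: Model, names, where: str):
    declared = {s.name for s in model.species}
    for n in names:
        if n not in declared:
            raise ValueError(f"undeclared species {n!r} referenced in {where}")


def bind_model(model: Model, mesh: TetMesh, measures: MeshMeasures | None = None) -> BoundModel:
    """Enumerate every kinetic process of ``model`` on ``mesh``.

    Deterministic: identical inputs give identical process catalogues.
    """
    if measures is None:
        measures = compute_measures(mesh)

    # species columns: volume species = all declared; surface species =
    # declared species (usable on patches) + channel states
    vol_species = [s.name for s in model.species]
    surf_species = [s.name for s in model.species]
    for p in model.patches:
        for chan, _ in p.channels:
            for st in chan.states:
                surf_species.append(chan.state_name(st))
    vidx = {n: i for i, n in enumerate(vol_species)}
    sidx = {n: i for i, n in enumerate(surf_species)}
    valence = {s.name: s.valence for s in model.species}

    processes: list[KineticProcess] = []
    diffusion: list[tuple[int, float, np.ndarray]] = []
    channel_counts: dict[tuple[int, str], np.ndarray] = {}

    for comp in model.compartments:
        if comp.name not in mesh.comp_names:
            raise ValueError(f"compartment tag {comp.name!r} not found in mesh "
                             f"(tags: {mesh.comp_names})")
        tets = mesh.comp_tets(comp.name)
        for rxn in comp.reactions:
            _check_species(model, list(rxn.lhs) + list(rxn.rhs), f"reaction in {comp.name}")
            if rxn.order < 1:
                raise ValueError("reactions need at least one reactant")
            for t in tets:
                c = stochastic_rate_constant(rxn.k, rxn.units, rxn.order,
                                             float(measures.volumes[t]))
                processes.append(KineticProcess(
                    pid=len(processes), kind="reaction", elem_kind="tet", elem=int(t),
                    reactants=tuple(("tet", int(t), vidx[s], n) for s, n in rxn.lhs.items() if n),
                    products=tuple(("tet", int(t), vidx[s], n) for s, n in rxn.rhs.items() if n),
                    c=c,
                ))
        for rule in comp.diffusion:
            _check_species(model, [rule.species], f"diffusion rule in {comp.name}")
            diffusion.append((vidx[rule.species], rule.D, tets))

    for patch in model.patches:
        if patch.name not in mesh.patch_names:
            raise ValueError(f"patch tag {patch.name!r} not found in mesh "
                             f"(tags: {mesh.patch_names})")
        tris = mesh.patch_tris(patch.name)
        inner = mesh.tri_tets[tris, 0]
        if np.any(inner < 0):
            raise ValueError(f"patch {patch.name!r} has triangles with no adjacent tet")
        ptag = mesh.patch_names.index(patch.name)

        for sr in patch.surface_reactions:
            _check_species(model, list(sr.lhs_vol) + list(sr.lhs_surf)
                           + list(sr.rhs_vol) + list(sr.rhs_surf),
                           f"surface reaction on {patch.name}")
            if sr.order < 1:
                raise ValueError("surface reactions need at least one reactant")
            for tri, tet in zip(tris, inner):
                c = stochastic_rate_constant(sr.k, sr.units, sr.order,
                                             float(measures.volumes[tet]))
                reac = tuple(("tet", int(tet), vidx[s], n) for s, n in sr.lhs_vol.items() if n) \
                    + tuple(("tri", int(tri), sidx[s], n) for s, n in sr.lhs_surf.items() if n)
                prod = tuple(("tet", int(tet), vidx[s], n) for s, n in sr.rhs_vol.items() if n) \
                    + tuple(("tri", int(tri), sidx[s], n) for s, n in sr.rhs_surf.items() if n)
                processes.append(KineticProcess(
                    pid=len(processes), kind="sreac", elem_kind="tri", elem=int(tri),
                    reactants=reac, products=prod, c=c,
                ))

        # channels: integer per-triangle populations, then one kinetic process
        # per transition per triangle (voltage-dependent)
        areas = measures.tri_areas[tris]
        rho = mesh.meta.get("surface_ratio", 1.0)
        for chan, density in patch.channels:
            total = int(round(density * rho * float(areas.sum())))
            per_tri = largest_remainder(areas, total)
            channel_counts[(ptag, chan.name)] = per_tri
            for tri, tet in zip(tris, inner):
                for src, dst, mult, fn in chan.transitions:
                    processes.append(KineticProcess(
                        pid=len(processes), kind="channel", elem_kind="tri", elem=int(tri),
                        reactants=(("tri", int(tri), sidx[chan.state_name(src)], 1),),
                        products=(("tri", int(tri), sidx[chan.state_name(dst)], 1),),
                        c=float(mult), rate_fn=fn, voltage_dep=True,
                    ))

        for flux in patch.ghk_fluxes:
            _check_species(model, [flux.ion], f"GHK flux on {patch.name}")
            for tri, tet in zip(tris, inner):
                vol = float(measures.volumes[tet])
                common = dict(elem_kind="tri", elem=int(tri), voltage_dep=True,
                              ghk=(flux.permeability, flux.valence, flux.c_out, vol))
                processes.append(KineticProcess(
                    pid=len(processes), kind="ghk_out",
                    reactants=(("tet", int(tet), vidx[flux.ion], 1),),
                    products=(), c=1.0, **common))
                processes.append(KineticProcess(
                    pid=len(processes), kind="ghk_in",
                    reactants=(), c=1.0,
                    products=(("tet", int(tet), vidx[flux.ion], 1),), **common))

    for memb in model.membranes:
        if memb.patch not in mesh.patch_names:
            raise ValueError(f"membrane patch tag {memb.patch!r} not found in mesh")

    return BoundModel(model, mesh, measures, vol_species, surf_species,
                      processes, diffusion, channel_counts, list(model.membranes))
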