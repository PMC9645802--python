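"""The nested time-window scheduler and user-facing simulation object.

A run from the current state time to ``T_end`` is split into EField windows
of length ``efield_dt`` (or one window spanning the whole call when no
membrane is declared).  Each EField window is subdivided into
reaction-diffusion windows of length ``dt_rd`` chosen from the mesh and
diffusion constants.  Within an RD window the SSA operator fires kinetic
events up to the window end, then the diffusion operator moves molecules and
synchronizes ΔM; at the end of each EField window the membrane potential is
advanced by one implicit step.  Window boundaries are computed as integer
multiples of the window length (no floating-point drift) and the state time
lands exactly on ``T_end``; control then returns to the caller for data
inquiry.

Emulated ranks: the mesh is partitioned, each rank owns the kinetic processes
of its tetrahedrons and draws from its own RNG stream (seeded ``seed+rank``);
diffusion stages cross-rank moves in ΔM exactly as a distributed run would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import diffusion as dfn
from .efield import VoltageState, assemble_efield_system, efield_step, ghk_current
from .geometry import Partition, compute_measures, partition_mesh
from .model import BoundModel, largest_remainder
from .ssa import KineticState
from .state import DeltaMoleculeState, MoleculeState


@dataclass
class Schedule:
    """Time-window parameters of the core loop."""

    efield_dt: float | None = None   # ΔT_EField (s); None -> one window per run call
    alpha_rd: float = 1.0            # safety factor on the RD window length

    def __post_init__(self):
        if self.efield_dt is not None and self.efield_dt <= 0:
            raise ValueError("efield_dt must be positive")
        if self.alpha_rd <= 0:
            raise ValueError("alpha_rd must be positive")


def _windows(t0: float, t1: float, dt: float):
    """Boundaries t0 + k*dt clipped to t1; lands exactly on t1."""
    if dt <= 0 or not np.isfinite(dt):
        yield t0, t1
        return
    n = max(1, math.ceil((t1 - t0) / dt - 1e-9))
    prev = t0
    for k in range(1, n + 1):
        nxt = t1 if k == n else t0 + k * dt
        yield prev, nxt
        prev = nxt


class Simulation:
    """Bound model + partition + state containers + operator scheduling."""

    def __init__(self, bound: BoundModel, schedule: Schedule | None = None,
                 seed: int = 0, ranks: int = 1, use_components: bool = False,
                 gating: str = "stochastic", ssa_method: str = "nrm",
                 temperature: float = 293.15, v_init: float | None = None,
                 log_phases: bool = False):
        self.bound = bound
        self.mesh = bound.mesh
        self.measures = bound.measures
        self.schedule = schedule or Schedule()
        self.seed = int(seed)
        self.temperature = temperature
        self.ssa_method = ssa_method
        self.gating = gating
        self.partition: Partition = partition_mesh(self.mesh, ranks, self.measures)
        self.rngs = [np.random.default_rng(self.seed + r) for r in range(ranks)]
        self._init_rng = np.random.default_rng(self.seed + ranks)
        self.t = 0.0
        self.phase_log: list[tuple[str, float]] | None = [] if log_phases else None
        self._started = False
        self._injections: list[tuple[np.ndarray, float]] = []
        self._det_gating: list[dict] = []
        self._v_init_override = v_init

        self._init_molecules()
        self._init_efield()
        self._init_kinetics(use_components)
        self.rates = dfn.compute_diffusion_rates(self.measures, bound.diffusion)
        self._dM = DeltaMoleculeState(self.mesh.num_tets, len(bound.vol_species),
                                      ranks)

    # -- construction -------------------------------------------------------

    def _init_molecules(self) -> None:
        b = self.bound
        self.M = MoleculeState(self.mesh.num_tets, len(b.vol_species),
                               self.mesh.num_tris, len(b.surf_species))
        for comp in b.model.compartments:
            tets = self.mesh.comp_tets(comp.name)
            w = self.measures.volumes[tets]
            for sp, total in comp.initial.items():
                draws = self._init_rng.multinomial(int(total), w / w.sum())
                self.M.vol[tets, b.vol_index(sp)] += draws
        for patch in b.model.patches:
            tris = self.mesh.patch_tris(patch.name)
            areas = self.measures.tri_areas[tris]
            ptag = self.mesh.patch_names.index(patch.name)
            for sp, total in patch.initial_surf.items():
                draws = self._init_rng.multinomial(int(total), areas / areas.sum())
                self.M.surf[tris, b.surf_index(sp)] += draws
            for chan, _density in patch.channels:
                per_tri = b.channel_counts[(ptag, chan.name)]
                v0_mV = self._v_init_guess() * 1e3
                if chan.init == "stationary":
                    frac = chan.stationary(v0_mV)
                else:
                    frac = np.array([1.0 if s == chan.init else 0.0
                                     for s in chan.states])
                if self.gating == "deterministic":
                    self._det_gating.append(dict(
                        chan=chan, tris=tris,
                        counts=per_tri.astype(float),
                        frac=np.tile(frac, (len(tris), 1)),
                        cache={},
                    ))
                else:
                    for tri, n in zip(tris, per_tri):
                        alloc = largest_remainder(frac, int(n))
                        for s, cnt in zip(chan.states, alloc):
                            self.M.surf[tri, b.surf_index(chan.state_name(s))] += cnt

    def _v_init_guess(self) -> float:
        if self._v_init_override is not None:
            return self._v_init_override
        if self.bound.membranes:
            return self.bound.membranes[0].leak_erev
        return 0.0

    def _init_efield(self) -> None:
        self.vs: VoltageState | None = None
        if not self.bound.membranes:
            return
        membranes = []
        for memb in self.bound.membranes:
            tris = self.mesh.patch_tris(memb.patch)
            from .efield import MembraneParams

            membranes.append((tris, MembraneParams(
                capacitance=memb.capacitance, leak_g=memb.leak_g,
                leak_erev=memb.leak_erev,
                resistivity=getattr(memb, "resistivity", 1.0))))
        self.vs = assemble_efield_system(self.mesh, self.measures, membranes,
                                         v_init=self._v_init_guess())

    def _init_kinetics(self, use_components: bool) -> None:
        b = self.bound
        owner = self.partition.owner
        tri_owner = np.full(self.mesh.num_tris, 0, dtype=np.int64)
        if self.mesh.num_tris:
            tri_owner = owner[np.where(self.mesh.tri_tets[:, 0] >= 0,
                                       self.mesh.tri_tets[:, 0], 0)]
        procs = b.processes
        if self.gating == "deterministic":
            procs = [kp for kp in procs if kp.kind != "channel"]
        self.K: list[KineticState] = []
        for r in range(self.partition.num_ranks):
            mine = [kp for kp in procs
                    if (owner[kp.elem] == r if kp.elem_kind == "tet"
                        else tri_owner[kp.elem] == r)]
            self.K.append(KineticState(mine, self.M, self.rngs[r],
                                       temperature=self.temperature,
                                       use_components=use_components))

    # -- configuration ------------------------------------------------------

    def add_injection(self, vertices: np.ndarray, amps: float) -> None:
        """Constant current (A) split over ``vertices`` by lumped area."""
        self._injections.append((np.asarray(vertices, dtype=np.int64), float(amps)))

    def nearest_vertex(self, coord) -> int:
        d = np.linalg.norm(self.mesh.vertices - np.asarray(coord, float), axis=1)
        return int(np.argmin(d))

    @property
    def event_count(self) -> int:
        return sum(k.event_count for k in self.K)

    # -- helpers ------------------------------------------------------------

    def _tri_voltage_mV(self) -> np.ndarray | None:
        if self.vs is None or self.mesh.num_tris == 0:
            return None
        return self.vs.triangle_voltage(self.mesh.tris) * 1e3

    def _injection_vector(self) -> np.ndarray | None:
        if not self._injections or self.vs is None:
            return None
        i_ext = np.zeros(self.vs.num_vertices)
        for verts, amps in self._injections:
            w = self.measures.vertex_tri_areas[verts]
            w = w / w.sum() if w.sum() > 0 else np.full(len(verts), 1.0 / len(verts))
            i_ext[verts] += amps * w
        return i_ext

    def _channel_terms(self):
        """Per-vertex (G, G*E, I_ghk) from current channel occupancies."""
        b = self.bound
        nv = self.mesh.num_vertices
        g = np.zeros(nv)
        ge = np.zeros(nv)
        i_ghk = np.zeros(nv)
        v_tri = None
        entries = []
        for patch in b.model.patches:
            tris = self.mesh.patch_tris(patch.name)
            ptag = self.mesh.patch_names.index(patch.name)
            for chan, _d in patch.channels:
                entries.append((patch, tris, ptag, chan))
        for patch, tris, ptag, chan in entries:
            det = next((d for d in self._det_gating if d["chan"] is chan),
                       None) if self.gating == "deterministic" else None
            for cur in chan.currents:
                sidx = chan.states.index(cur.state)
                if det is not None:
                    open_counts = det["counts"] * det["frac"][:, sidx]
                else:
                    col = self.bound.surf_index(chan.state_name(cur.state))
                    open_counts = self.M.surf[tris, col].astype(float)
                if cur.kind == "ohmic":
                    g_tri = cur.g_single * open_counts
                    np.add.at(g, self.mesh.tris[tris].ravel(),
                              np.repeat(g_tri / 3.0, 3))
                    np.add.at(ge, self.mesh.tris[tris].ravel(),
                              np.repeat(g_tri * cur.erev / 3.0, 3))
                elif cur.kind == "ghk":
                    if v_tri is None:
                        v_tri = self.vs.triangle_voltage(self.mesh.tris)
                    ion = self.bound.vol_index(cur.ion)
                    zval = next(s.valence for s in b.model.species
                                if s.name == cur.ion)
                    inner = self.mesh.tri_tets[tris, 0]
                    c_in = (self.M.vol[inner, ion]
                            / (6.02214076e23 * self.measures.volumes[inner]))
                    i_tri = -open_counts * ghk_current(
                        cur.permeability, zval, v_tri[tris], c_in, cur.c_out,
                        self.temperature)
                    np.add.at(i_ghk, self.mesh.tris[tris].ravel(),
                              np.repeat(i_tri / 3.0, 3))
        return g, ge, i_ghk

    def _advance_det_gating(self, dt: float) -> None:
        """Mean-field gating: advance state fractions by one RK4 step.

        The deterministic (infinite-channel) limit of the stochastic gating
        chain is df/dt = f Q(V) per triangle; one classical RK4 step per
        EField window (dt * max rate << 1 at 5 µs) is ample.
        """
        v_tri = self._tri_voltage_mV()
        for d in self._det_gating:
            chan = d["chan"]
            v = v_tri[d["tris"]]
            n = len(chan.states)
            idx = {s: i for i, s in enumerate(chan.states)}
            Q = np.zeros((len(v), n, n))
            for src, dst, mult, fn in chan.transitions:
                r = mult * np.asarray(fn(v), dtype=float)
                i, j = idx[src], idx[dst]
                Q[:, i, j] += r
                Q[:, i, i] -= r
            f = d["frac"]

            def rhs(fr):
                return np.einsum("ts,tsj->tj", fr, Q)

            k1 = rhs(f)
            k2 = rhs(f + 0.5 * dt * k1)
            k3 = rhs(f + 0.5 * dt * k2)
            k4 = rhs(f + dt * k3)
            d["frac"] = f + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    def _log(self, phase: str) -> None:
        if self.phase_log is not None:
            self.phase_log.append((phase, self.t))

    # -- the core loop ------------------------------------------------------

    def run(self, t_end: float) -> "Simulation":
        """Advance the state to exactly ``t_end``."""
        if t_end < self.t - 1e-15:
            raise ValueError(f"t_end {t_end} is before current state time {self.t}")
        if t_end <= self.t:
            return self

        if not self._started:
            v_tri = self._tri_voltage_mV()
            for k in self.K:
                k.initialize(self.t, v_tri)
            self._started = True

        has_ef = self.vs is not None
        ef_dt = self.schedule.efield_dt if (has_ef and self.schedule.efield_dt) \
            else (t_end - self.t)
        rd_dt = dfn.select_rd_dt(self.rates, ef_dt, self.schedule.alpha_rd)

        for ta, tb in _windows(self.t, t_end, ef_dt):
            v_tri = self._tri_voltage_mV()
            if v_tri is not None:
                for k in self.K:
                    k.set_voltage(v_tri, ta)
            for ra, rb in _windows(ta, tb, rd_dt):
                self._log("ssa")
                for k in self.K:
                    k.run_window(ra, rb, method=self.ssa_method)
                self.t = rb
                self._log("diffusion")
                changed = dfn.diffuse_window(self.M, self.rates, rb - ra,
                                             self.partition, self.rngs, self._dM)
                self._log("diffusion_sync")
                if changed:
                    for k in self.K:
                        k.notify_keys(changed, rb)
            if has_ef:
                # snap float jitter in the window length so the factorization
                # cache hits on every full-length window
                ef_len = tb - ta
                if abs(ef_len - ef_dt) < 1e-9 * ef_dt:
                    ef_len = ef_dt
                if self.gating == "deterministic":
                    self._advance_det_gating(ef_len)
                g, ge, i_ghk = self._channel_terms()
                i_ext = self._injection_vector()
                i_tot = i_ghk if i_ext is None else i_ghk + i_ext
                self._log("efield")
                efield_step(self.vs, ef_len,
                            g_extra=g if g.any() else None,
                            ge_extra=ge if ge.any() else None,
                            i_ext=i_tot if i_tot.any() else None)
            self.t = tb
        return self

    # -- recording driver ---------------------------------------------------

    def run_record(self, t_end: float, record_dt: float,
                   probes: dict[str, int]):
        """Loop ``run`` over recording intervals; sample probe vertices.

        Returns (times, {probe: voltage array}).  Recording happens between
        run calls, when control is back with the caller.
        """
        if self.vs is None:
            raise ValueError("recording probes requires a membrane/EField model")
        n = max(1, round((t_end - self.t) / record_dt))
        t0 = self.t
        times = [self.t]
        out = {name: [self.vs.v[v]] for name, v in probes.items()}
        for k in range(1, n + 1):
            self.run(t_end if k == n else t0 + k * record_dt)
            times.append(self.t)
            for name, v in probes.items():
                out[name].append(self.vs.v[v])
        return np.asarray(times), {k: np.asarray(v) for k, v in out.items()}
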