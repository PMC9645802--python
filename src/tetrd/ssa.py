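"""Kinetic-process state K and the stochastic simulation operators.

The catalogue of kinetic processes (volume reactions, surface reactions,
channel-state transitions, stochastic GHK ion crossings) is evolved within
each reaction-diffusion window by an exact SSA.  The default operator is the
Gibson-Bruck next-reaction method (NRM): every process carries an absolute
next-firing time in a priority queue; firing a process redraws its time, and
a propensity change of a pending process rescales its remaining waiting time
by ``a_old / a_new``.  A plain direct-method (Gillespie) operator is provided
as an interchangeable alternative; the two are distributionally identical.

Events drawn beyond the window end are *not* applied: their queue times
persist into later windows, which is exact under NRM absolute-time semantics.
Voltage-dependent propensities are frozen during a window and refreshed in
bulk at the start of every EField window.

The dependency graph (edge p -> q when firing p changes a count entering q's
propensity) is also built here; its weakly connected components can be
evolved by independent queues within a window (the independent-graph
optimization), which changes performance but not statistics.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

Key = tuple[str, int, int]  # (location "tet"/"tri", element, species column)


@dataclass
class KineticProcess:
    """One stochastic event type bound to a mesh element.

    ``reactants``/``products`` are tuples of (loc, element, species, stoich).
    Propensity: ``a = coef * combinations`` with mass-action combination
    counts (n, n*m, or n(n-1)/2 for identical reactants).  ``coef`` is ``c``
    for plain reactions, ``c * rate_fn(V)`` for channel transitions, and a
    GHK unidirectional-flux coefficient for ghk_in/ghk_out processes.
    """

    pid: int
    kind: str                      # "reaction" | "sreac" | "channel" | "ghk_in" | "ghk_out"
    elem_kind: str
    elem: int
    reactants: tuple
    products: tuple
    c: float
    rate_fn: object = None         # callable mV -> s^-1 (channel transitions)
    voltage_dep: bool = False
    ghk: tuple | None = None       # (permeability m^3/s, valence, c_out mol/m^3, tet volume m^3)

    @property
    def order(self) -> int:
        return sum(r[3] for r in self.reactants)

    def net_changes(self) -> dict[Key, int]:
        delta: dict[Key, int] = {}
        for loc, elem, sp, n in self.reactants:
            delta[(loc, elem, sp)] = delta.get((loc, elem, sp), 0) - n
        for loc, elem, sp, n in self.products:
            delta[(loc, elem, sp)] = delta.get((loc, elem, sp), 0) + n
        return {k: v for k, v in delta.items() if v != 0}

    def read_keys(self) -> list[Key]:
        return [(loc, elem, sp) for loc, elem, sp, _ in self.reactants]


def _combinations(kp: KineticProcess, vol: np.ndarray, surf: np.ndarray) -> float:
    comb = 1.0
    for loc, elem, sp, stoich in kp.reactants:
        n = vol[elem, sp] if loc == "tet" else surf[elem, sp]
        if stoich == 1:
            comb *= n
        elif stoich == 2:
            comb *= n * (n - 1) / 2.0
        else:
            raise ValueError("stoichiometries above 2 are not supported")
    return comb


def _ghk_coef(kp: KineticProcess, v_volts: float, temperature: float) -> float:
    """Unidirectional GHK crossing rate coefficient.

    Efflux of ions from the inner tet at count n is ``coef_out * n`` with
    ``coef_out = P * phi(u) / V_tet`` and ``u = zFV/RT``,
    ``phi(u) = u / (1 - e^-u)`` (one-way constant-field flux).  Influx is
    count-independent: ``coef_in = P * phi(-u) * c_out * N_A``.
    """
    from scipy.constants import Avogadro, R
    from scipy.constants import physical_constants

    F = physical_constants["Faraday constant"][0]
    P, z, c_out, vol = kp.ghk
    u = z * F * v_volts / (R * temperature)

    def phi(x):
        if abs(x) < 1e-9:
            return 1.0 + x / 2.0
        return x / -math.expm1(-x)

    if kp.kind == "ghk_out":
        return P * phi(u) / vol
    return P * phi(-u) * c_out * Avogadro


def compute_propensity(kp: KineticProcess, M, v_tri_mV=None,
                       temperature: float = 293.15) -> float:
    """Propensity of a single process against a molecule state.

    ``M`` is a :class:`~tetrd.state.MoleculeState`; voltage-dependent
    processes need the per-triangle potential (mV).
    """
    coef = kp.c
    if kp.voltage_dep:
        if v_tri_mV is None:
            raise ValueError(f"process {kp.pid} is voltage-dependent; supply v_tri_mV")
        v = float(np.asarray(v_tri_mV).ravel()[kp.elem] if np.ndim(v_tri_mV) else v_tri_mV)
        if kp.ghk is not None:
            coef = kp.c * _ghk_coef(kp, v * 1e-3, temperature)
        else:
            coef = kp.c * float(kp.rate_fn(v))
    return coef * _combinations(kp, M.vol, M.surf)


# ---------------------------------------------------------------------------
# dependency graph

def build_dependency_graph(processes: list[KineticProcess]):
    """Directed graph: p -> q when firing p changes a reactant count of q."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(kp.pid for kp in processes)
    readers: dict[Key, list[int]] = {}
    for kp in processes:
        for key in kp.read_keys():
            readers.setdefault(key, []).append(kp.pid)
    for kp in processes:
        targets = set()
        for key in kp.net_changes():
            targets.update(readers.get(key, ()))
        for q in sorted(targets):
            g.add_edge(kp.pid, q)
    return g


def split_components(graph) -> list[list[int]]:
    """Weakly connected components, each sorted, ordered by smallest member."""
    import networkx as nx

    comps = [sorted(c) for c in nx.weakly_connected_components(graph)]
    return sorted(comps, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# next-reaction queue

class NrmQueue:
    """Min-queue of absolute next-firing times with lazy invalidation.

    The authoritative time of process i is ``times[i]`` (+inf when inactive);
    heap entries are (time, pid) snapshots, discarded on pop when stale.
    Ties break on pid, so a fixed seed gives a fixed event order.
    """

    def __init__(self, times: np.ndarray, members: np.ndarray | None = None):
        self.times = times
        self.members = members if members is not None else np.arange(len(times))
        self.rebuild()

    def rebuild(self) -> None:
        t = self.times[self.members]
        fin = np.isfinite(t)
        self.heap = list(zip(t[fin].tolist(),
                             np.asarray(self.members)[fin].tolist()))
        heapq.heapify(self.heap)

    def push(self, pid: int) -> None:
        if np.isfinite(self.times[pid]):
            heapq.heappush(self.heap, (float(self.times[pid]), int(pid)))

    def peek(self):
        h = self.heap
        while h:
            t, pid = h[0]
            if self.times[pid] == t:
                return t, pid
            heapq.heappop(h)
        return None

    def pop(self):
        nxt = self.peek()
        if nxt is not None:
            heapq.heappop(self.heap)
        return nxt


# ---------------------------------------------------------------------------
# kinetic state

class KineticState:
    """Propensities, dependency tables and queues for one emulated rank."""

    def __init__(self, processes: list[KineticProcess], M, rng,
                 temperature: float = 293.15, use_components: bool = False,
                 log_events: bool = False):
        self.procs = list(processes)
        self.M = M
        self.rng = rng
        self.temperature = temperature
        self.use_components = use_components
        self.n = len(self.procs)
        self.a = np.zeros(self.n)
        self.coef = np.array([kp.c for kp in self.procs], dtype=float)
        self.times = np.full(self.n, np.inf)
        self.event_count = 0
        self.event_log: list[tuple[float, int, int]] | None = [] if log_events else None

        # dependency tables (local indices)
        readers: dict[Key, list[int]] = {}
        for i, kp in enumerate(self.procs):
            for key in kp.read_keys():
                readers.setdefault(key, []).append(i)
        self.readers = {k: np.asarray(v, dtype=np.int64) for k, v in readers.items()}
        deps = []
        for kp in self.procs:
            targets: set[int] = set()
            for key in kp.net_changes():
                targets.update(self.readers.get(key, np.empty(0, np.int64)).tolist())
            deps.append(sorted(targets))
        from .flatmm import FlatMultimap

        self.deps = FlatMultimap.from_lists(deps, dtype=np.int64)

        # components via union-find over write->read links
        parent = list(range(self.n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(self.n):
            for j in self.deps[i]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri
        self.comp_of = np.fromiter((find(i) for i in range(self.n)), dtype=np.int64,
                                   count=self.n)
        roots = {r: k for k, r in enumerate(dict.fromkeys(self.comp_of.tolist()))}
        self.comp_of = np.asarray([roots[r] for r in self.comp_of], dtype=np.int64)
        self.num_components = len(roots)

        # voltage-dependent bookkeeping for bulk refresh
        vd = [i for i, kp in enumerate(self.procs) if kp.voltage_dep]
        self.v_pids = np.asarray(vd, dtype=np.int64)
        groups: dict[int, list[int]] = {}
        for i in vd:
            kp = self.procs[i]
            if kp.ghk is None:
                groups.setdefault(id(kp.rate_fn), []).append(i)
        self.chan_groups = []
        for ids in groups.values():
            arr = np.asarray(ids, dtype=np.int64)
            kps = [self.procs[i] for i in ids]
            self.chan_groups.append((
                kps[0].rate_fn, arr,
                np.asarray([kp.elem for kp in kps], dtype=np.int64),
                np.asarray([kp.c for kp in kps], dtype=float),
            ))
        self.ghk_pids = np.asarray([i for i in vd if self.procs[i].ghk is not None],
                                   dtype=np.int64)
        # gather tables for the vectorized bulk refresh: every voltage proc
        # has at most one order-1 reactant (channel source state / GHK ion)
        loc, elem, sp, slow = [], [], [], []
        for i in vd:
            kp = self.procs[i]
            if len(kp.reactants) == 0:
                loc.append(2), elem.append(0), sp.append(0)
            elif len(kp.reactants) == 1 and kp.reactants[0][3] == 1:
                r = kp.reactants[0]
                loc.append(0 if r[0] == "tet" else 1), elem.append(r[1]), sp.append(r[2])
            else:
                loc.append(3), elem.append(0), sp.append(0)
                slow.append(i)
        self.v_loc = np.asarray(loc, dtype=np.int64)
        self.v_elem = np.asarray(elem, dtype=np.int64)
        self.v_sp = np.asarray(sp, dtype=np.int64)
        self.v_slow = slow  # rare shapes, recomputed scalar-wise
        self.queues: list[NrmQueue] = []

    # -- propensities -------------------------------------------------------

    def recompute_propensity(self, i: int) -> float:
        """a_i from the cached coefficient and current counts."""
        a = self.coef[i] * _combinations(self.procs[i], self.M.vol, self.M.surf)
        self.a[i] = a
        return a

    def recompute_all(self) -> np.ndarray:
        for i in range(self.n):
            self.recompute_propensity(i)
        return self.a

    def full_recomputation(self, v_tri_mV=None) -> np.ndarray:
        """Propensities from scratch (independent of the caches) — for checks."""
        return np.asarray([
            compute_propensity(kp, self.M, v_tri_mV, self.temperature)
            for kp in self.procs
        ])

    # -- initialization and updates ----------------------------------------

    def initialize(self, t: float, v_tri_mV=None) -> None:
        if len(self.v_pids) and v_tri_mV is None:
            raise ValueError("voltage-dependent processes need an initial voltage")
        if v_tri_mV is not None:
            self._refresh_voltage_coefs(v_tri_mV)
        self.recompute_all()
        with np.errstate(divide="ignore"):
            draws = self.rng.exponential(size=self.n)
            self.times = np.where(self.a > 0, t + draws / np.where(self.a > 0, self.a, 1.0),
                                  np.inf)
        self._build_queues()

    def _build_queues(self) -> None:
        if self.use_components and self.num_components > 1:
            members = [np.flatnonzero(self.comp_of == c) for c in range(self.num_components)]
            self.queues = [NrmQueue(self.times, m) for m in members]
        else:
            self.queues = [NrmQueue(self.times)]

    def _refresh_voltage_coefs(self, v_tri_mV) -> None:
        v_tri_mV = np.asarray(v_tri_mV, dtype=float)
        for fn, pids, tris, mult in self.chan_groups:
            self.coef[pids] = mult * fn(v_tri_mV[tris])
        for i in self.ghk_pids:
            kp = self.procs[i]
            self.coef[i] = kp.c * _ghk_coef(kp, float(v_tri_mV[kp.elem]) * 1e-3,
                                            self.temperature)

    def set_voltage(self, v_tri_mV, t_now: float) -> None:
        """Bulk refresh of voltage-dependent propensities at a window start.

        Pending times are rescaled by a_old/a_new (NRM), inactive processes
        park at +inf, resuscitated ones draw fresh waiting times; the queues
        are then rebuilt wholesale.
        """
        if not len(self.v_pids):
            return
        self._refresh_voltage_coefs(v_tri_mV)
        pids = self.v_pids
        a_old = self.a[pids].copy()
        comb = np.ones(len(pids))
        tet_mask = self.v_loc == 0
        tri_mask = self.v_loc == 1
        comb[tet_mask] = self.M.vol[self.v_elem[tet_mask], self.v_sp[tet_mask]]
        comb[tri_mask] = self.M.surf[self.v_elem[tri_mask], self.v_sp[tri_mask]]
        self.a[pids] = self.coef[pids] * comb
        for i in self.v_slow:
            self.recompute_propensity(i)
        a_new = self.a[pids]
        t_old = self.times[pids]
        new_t = np.full(len(pids), np.inf)
        both = (a_old > 0) & (a_new > 0) & np.isfinite(t_old)
        new_t[both] = t_now + (a_old[both] / a_new[both]) * (t_old[both] - t_now)
        fresh = (a_new > 0) & ~both
        if fresh.any():
            new_t[fresh] = t_now + self.rng.exponential(size=int(fresh.sum())) / a_new[fresh]
        self.times[pids] = new_t
        for q in self.queues:
            q.rebuild()

    def _nrm_update(self, i: int, a_old: float, t_now: float, fired: bool) -> None:
        a_new = self.recompute_propensity(i)
        if fired:
            self.times[i] = (t_now + self.rng.exponential() / a_new) if a_new > 0 else np.inf
        elif a_new <= 0:
            self.times[i] = np.inf
        elif a_old <= 0 or not np.isfinite(self.times[i]):
            self.times[i] = t_now + self.rng.exponential() / a_new
        else:
            self.times[i] = t_now + (a_old / a_new) * (self.times[i] - t_now)
        q = self.queues[self.comp_of[i]] if len(self.queues) > 1 else self.queues[0]
        q.push(i)

    def notify_keys(self, keys, t_now: float) -> None:
        """Counts changed externally (diffusion): update dependent processes."""
        touched: set[int] = set()
        for key in keys:
            arr = self.readers.get(key)
            if arr is not None:
                touched.update(arr.tolist())
        for i in sorted(touched):
            self._nrm_update(i, self.a[i], t_now, fired=False)

    # -- event application --------------------------------------------------

    def _apply(self, i: int) -> None:
        kp = self.procs[i]
        for loc, elem, sp, stoich in kp.reactants:
            arr = self.M.vol if loc == "tet" else self.M.surf
            arr[elem, sp] -= stoich
            if arr[elem, sp] < 0:
                raise RuntimeError(
                    f"negative count after event of process {kp.pid} "
                    f"at {loc} {elem}, species {sp}")
        for loc, elem, sp, stoich in kp.products:
            arr = self.M.vol if loc == "tet" else self.M.surf
            arr[elem, sp] += stoich

    # -- window drivers -----------------------------------------------------

    def run_window(self, t_start: float, t_end: float, method: str = "nrm") -> None:
        if t_end < t_start:
            raise ValueError("t_end must be >= t_start")
        if method == "nrm":
            for q in self.queues:
                self._run_nrm(q, t_end)
        elif method == "direct":
            self._run_direct(t_start, t_end)
        else:
            raise ValueError(f"unknown SSA method {method!r}")

    def _run_nrm(self, q: NrmQueue, t_end: float) -> None:
        while True:
            nxt = q.peek()
            if nxt is None or nxt[0] > t_end:
                break
            t, i = q.pop()
            self._apply(i)
            self.event_count += 1
            if self.event_log is not None:
                self.event_log.append((t, self.procs[i].pid, self.procs[i].elem))
            a_old_i = self.a[i]
            for j in self.deps[i]:
                j = int(j)
                if j == i:
                    continue
                self._nrm_update(j, self.a[j], t, fired=False)
            self._nrm_update(i, a_old_i, t, fired=True)

    def _run_direct(self, t_start: float, t_end: float) -> None:
        """Direct-method reference operator (no queue; fresh draws each step)."""
        t = t_start
        while True:
            a_tot = float(self.a.sum())
            if a_tot <= 0:
                break
            t = t + self.rng.exponential() / a_tot
            if t > t_end:
                break
            r = self.rng.random() * a_tot
            i = int(np.searchsorted(np.cumsum(self.a), r, side="right"))
            i = min(i, self.n - 1)
            self._apply(i)
            self.event_count += 1
            if self.event_log is not None:
                self.event_log.append((t, self.procs[i].pid, self.procs[i].elem))
            for j in self.deps[i]:
                self.recompute_propensity(int(j))
        # direct method keeps no queue; times stay unused
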