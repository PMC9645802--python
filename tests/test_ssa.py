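"""Propensities, dependency graph, next-reaction queue and SSA statistics.

Stochastic assertions use fixed seeds and 3-sigma Monte-Carlo bands around
closed-form chemical-master-equation results; distributional equivalence of
operator variants is checked with a two-sample Cramér-von Mises test.
"""

import numpy as np
import pytest
from scipy import stats as sps

from tetrd import (bind_model, build_dependency_graph, compute_measures,
                   compute_propensity, split_components)
from tetrd.fixtures import two_tet_mesh
from tetrd.model import Compartment, Model, Reaction, Species
from tetrd.ssa import KineticProcess, KineticState, NrmQueue
from tetrd.state import MoleculeState


def kproc(pid, reactants, products, c, elem=0):
    return KineticProcess(pid=pid, kind="reaction", elem_kind="tet", elem=elem,
                          reactants=reactants, products=products, c=c)


def make_state(counts, procs, seed=0, **kw):
    M = MoleculeState(len(counts), len(counts[0]))
    M.vol[:] = counts
    K = KineticState(procs, M, np.random.default_rng(seed), **kw)
    return M, K


class TestPropensity:
    def test_exhausted_reactant(self):
        kp = kproc(0, (("tet", 0, 0, 1),), (("tet", 0, 1, 1),), c=10.0)
        M = MoleculeState(1, 2)
        assert compute_propensity(kp, M) == 0.0

    def test_bimolecular_distinct(self):
        kp = kproc(0, (("tet", 0, 0, 1), ("tet", 0, 1, 1)), (), c=2.0)
        M = MoleculeState(1, 2)
        M.vol[0] = [3, 4]
        assert compute_propensity(kp, M) == 24.0

    def test_bimolecular_identical_pairs(self):
        # A + A: n(n-1)/2 combinations, not n^2/2
        kp = kproc(0, (("tet", 0, 0, 2),), (), c=2.0)
        M = MoleculeState(1, 1)
        M.vol[0, 0] = 5
        assert compute_propensity(kp, M) == 2.0 * 5 * 4 / 2

    def test_first_order(self):
        kp = kproc(0, (("tet", 0, 0, 1),), (), c=3.0)
        M = MoleculeState(1, 1)
        M.vol[0, 0] = 7
        assert compute_propensity(kp, M) == 21.0


class TestDependencyGraph:
    def test_toy_graph_components(self, toy_bound):
        g = build_dependency_graph(toy_bound.processes)
        assert g.number_of_nodes() == 10
        comps = split_components(g)
        assert sorted(len(c) for c in comps) == [3, 7]

    def test_disjoint_reactions_no_cross_edges(self):
        pa = kproc(0, (("tet", 0, 0, 1),), (("tet", 0, 1, 1),), 1.0)
        pb = kproc(1, (("tet", 0, 2, 1),), (("tet", 0, 3, 1),), 1.0)
        g = build_dependency_graph([pa, pb])
        assert not g.has_edge(0, 1) and not g.has_edge(1, 0)
        assert g.has_edge(0, 0) and g.has_edge(1, 1)

    def test_randomized_edges_match_brute_force(self, rng):
        for _ in range(30):
            procs = []
            for pid in range(rng.integers(2, 10)):
                reac = tuple(("tet", int(rng.integers(0, 2)),
                              int(rng.integers(0, 4)), 1)
                             for _ in range(rng.integers(1, 3)))
                prod = tuple(("tet", int(rng.integers(0, 2)),
                              int(rng.integers(0, 4)), 1)
                             for _ in range(rng.integers(0, 3)))
                procs.append(kproc(pid, reac, prod, 1.0))
            g = build_dependency_graph(procs)
            for p in procs:
                for q in procs:
                    expect = bool(set(p.net_changes()) & set(q.read_keys()))
                    assert g.has_edge(p.pid, q.pid) == expect

    def test_engine_deps_match_graph(self, toy_bound):
        M = MoleculeState(2, 3, 1, len(toy_bound.surf_species))
        K = KineticState(toy_bound.processes, M, np.random.default_rng(0))
        g = build_dependency_graph(toy_bound.processes)
        for i, kp in enumerate(toy_bound.processes):
            assert sorted(K.deps[i].tolist()) == sorted(g.successors(kp.pid))

    def test_component_extremes(self):
        chain = [kproc(i, (("tet", 0, 0, 1),), (("tet", 0, 1, 1),), 1.0)
                 for i in range(4)]  # everyone consumes species 0
        g = build_dependency_graph(chain)
        assert len(split_components(g)) == 1
        isolated = [kproc(i, (("tet", 0, i, 1),), (), 1.0) for i in range(5)]
        g = build_dependency_graph(isolated)
        assert len(split_components(g)) == 5


class TestNrmQueue:
    def test_pop_order_and_ties_by_id(self):
        times = np.array([3.0, 1.0, 1.0, np.inf])
        q = NrmQueue(times)
        assert q.pop() == (1.0, 1)
        assert q.pop() == (1.0, 2)
        assert q.pop() == (3.0, 0)
        assert q.pop() is None  # inf never appears

    def test_stale_entries_discarded(self):
        times = np.array([2.0, 5.0])
        q = NrmQueue(times)
        times[0] = 7.0
        q.push(0)
        assert q.pop() == (5.0, 1)
        assert q.pop() == (7.0, 0)


def _ab_model(n_total, kf=1.0, kb=1.0):
    model = Model(
        species=[Species("A"), Species("B")],
        compartments=[Compartment(
            name="comp",
            reactions=[Reaction({"A": 1}, {"B": 1}, kf),
                       Reaction({"B": 1}, {"A": 1}, kb)],
            initial={"A": n_total})],
    )
    return model


class TestWindowSemantics:
    def test_zero_propensities_advance_time(self):
        M, K = make_state([[0]], [kproc(0, (("tet", 0, 0, 1),), (), 1.0)])
        K.initialize(0.0)
        K.run_window(0.0, 5.0)
        assert K.event_count == 0

    def test_events_nondecreasing_and_within_window(self, toy_bound_no_ghk):
        M = MoleculeState(2, 3, 1, len(toy_bound_no_ghk.surf_species))
        M.vol[:] = [[50, 50, 50], [50, 50, 50]]
        K = KineticState(toy_bound_no_ghk.processes, M,
                         np.random.default_rng(7), log_events=True)
        K.initialize(0.0)
        K.run_window(0.0, 0.3)
        t = [e[0] for e in K.event_log]
        assert all(x <= y for x, y in zip(t, t[1:]))
        assert t and t[-1] <= 0.3

    def test_incremental_equals_full_recomputation(self, toy_bound_no_ghk):
        M = MoleculeState(2, 3, 1, len(toy_bound_no_ghk.surf_species))
        M.vol[:, :] = 30
        K = KineticState(toy_bound_no_ghk.processes, M, np.random.default_rng(3))
        K.initialize(0.0)
        K.run_window(0.0, 1.0)
        assert np.allclose(K.a, K.full_recomputation(), rtol=1e-12, atol=0)

    def test_negative_count_is_internal_error(self):
        M, K = make_state([[5]], [kproc(0, (("tet", 0, 0, 1),), (), 1.0)])
        K.initialize(0.0)
        M.vol[0, 0] = 0  # corrupt the state behind the operator's back
        with pytest.raises(RuntimeError, match="negative"):
            K.run_window(0.0, 100.0)


class TestCmeStatistics:
    def test_pure_decay_mean(self):
        # A -> 0 at k=1: E[n(t)] = n0 exp(-t)
        n0, t, reps = 1000, 1.0, 200
        rng = np.random.default_rng(11)
        finals = []
        for r in range(reps):
            M, K = make_state([[n0]], [kproc(0, (("tet", 0, 0, 1),), (), 1.0)],
                              seed=1000 + r)
            K.initialize(0.0)
            K.run_window(0.0, t)
            finals.append(M.vol[0, 0])
        mean = np.mean(finals)
        expect = n0 * np.exp(-1.0)
        sigma = np.sqrt(n0 * np.exp(-1) * (1 - np.exp(-1)) / reps)
        assert abs(mean - expect) < 3 * sigma

    def test_reversible_stationary_binomial(self):
        # A <-> B symmetric: stationary A ~ Binomial(N, 1/2)
        N, reps = 200, 200
        finals = []
        for r in range(reps):
            model = _ab_model(N)
            mesh = two_tet_mesh()
            bound = bind_model(model, mesh)
            M = MoleculeState(2, 2)
            M.vol[0, 0] = N  # all A in tet 0
            K = KineticState([kp for kp in bound.processes if kp.elem == 0],
                             M, np.random.default_rng(5000 + r))
            K.initialize(0.0)
            K.run_window(0.0, 5.0)  # ~10 relaxation times
            finals.append(M.vol[0, 0])
        mean, var = np.mean(finals), np.var(finals, ddof=1)
        assert abs(mean - N / 2) < 3 * np.sqrt((N / 4) / reps)
        # variance of a variance estimate: ~ var * sqrt(2/(reps-1))
        assert abs(var - N / 4) < 4 * (N / 4) * np.sqrt(2 / (reps - 1))


def _end_counts(method, reps, seed0, use_components=False):
    mesh = two_tet_mesh()
    bound = bind_model(_ab_model(60), mesh)
    out = []
    for r in range(reps):
        M = MoleculeState(2, 2)
        M.vol[0, 0] = 60
        K = KineticState([kp for kp in bound.processes if kp.elem == 0], M,
                         np.random.default_rng(seed0 + r),
                         use_components=use_components)
        K.initialize(0.0)
        K.run_window(0.0, 1.0, method=method)
        out.append(M.vol[0, 0])
    return np.asarray(out, dtype=float)


class TestOperatorEquivalence:
    def test_nrm_vs_direct_distribution(self):
        a = _end_counts("nrm", 300, 10_000)
        b = _end_counts("direct", 300, 20_000)
        res = sps.cramervonmises_2samp(a, b)
        assert res.pvalue > 1e-3

    def test_components_on_off_distribution(self):
        a = _end_counts("nrm", 300, 30_000, use_components=False)
        b = _end_counts("nrm", 300, 40_000, use_components=True)
        res = sps.cramervonmises_2samp(a, b)
        assert res.pvalue > 1e-3

    def test_components_partition_processes(self, toy_bound_no_ghk):
        M = MoleculeState(2, 3, 1, len(toy_bound_no_ghk.surf_species))
        K = KineticState(toy_bound_no_ghk.processes, M,
                         np.random.default_rng(0), use_components=True)
        assert K.num_components == 2
        sizes = sorted(np.bincount(K.comp_of).tolist())
        assert sizes == [3, 5]  # without GHK: 3-cycle and 3-cycle + 2 sreacs
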