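"""End-to-end validation workflows.

These functions run the full simulator on the benchmark fixtures and reduce
the results to the headline validation numbers: the passive-cable mean
squared error against the analytic solution, the deterministic-limit
Hodgkin-Huxley comparison against an ODE oracle, the scaled stochastic
spike check, and the batched-CVM null experiment.  They are used both by the
test suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import bind_model
from .coreloop import Schedule, Simulation
from .fixtures import (CableParams, rallpack1_fixture, rallpack3_fixture,
                       two_tet_mesh)
from .model import Compartment, Model, Reaction, Species
from .ssa import KineticState
from .state import MoleculeState
from .stats import cvm_batch_compare, detect_peaks, rallpack1_analytic


def rallpack1_mse(axial_segments: int = 200, t_end: float = 0.25,
                  seed: int = 0):
    """Run the passive cable and return (mse_zmin, mse_zmax) in mV^2.

    The membrane potential is recorded at both cable ends at every EField
    step (5 us) and compared against the analytic cable-equation series.
    """
    model, mesh, p = rallpack1_fixture(axial_segments)
    sim = Simulation(bind_model(model, mesh), Schedule(efield_dt=p.efield_dt),
                     seed=seed)
    z = mesh.vertices[:, 2]
    sim.add_injection(np.flatnonzero(np.isclose(z, 0.0)), p.current)
    probes = {"zmin": sim.nearest_vertex([0, 0, 0]),
              "zmax": sim.nearest_vertex([0, 0, p.length])}
    times, rec = sim.run_record(t_end, p.efield_dt, probes)
    mse = {}
    for name, x in (("zmin", 0.0), ("zmax", p.length)):
        analytic = rallpack1_analytic(p, x, times)
        mse[name] = float(np.mean(((rec[name] - analytic) * 1e3) ** 2))
    return mse["zmin"], mse["zmax"], mesh.num_tets


def hh_deterministic_limit_error(span: float = 0.01, efield_dt: float = 2e-6,
                                 current: float = 3e-11,
                                 record_dt: float = 1e-4):
    """Max |V_sim - V_ode| (volts) for a space-clamped HH patch.

    A 10 um stub cable with deterministic (mean-field) gating is driven past
    threshold; the oracle is a high-accuracy ODE integration of the classic
    four-variable Hodgkin-Huxley system with matching constants and the
    ideal-cylinder membrane area.
    """
    from scipy.integrate import solve_ivp

    from . import ratefns as rf

    L = 10e-6
    p = CableParams(length=L, current=current)
    model, mesh, _ = rallpack3_fixture(g_single=4e-12, axial_segments=10,
                                       params=p)
    sim = Simulation(bind_model(model, mesh), Schedule(efield_dt=efield_dt),
                     seed=0, gating="deterministic")
    z = mesh.vertices[:, 2]
    sim.add_injection(np.flatnonzero(np.isclose(z, 0.0)), p.current)
    times, rec = sim.run_record(span, record_dt,
                                {"v": sim.nearest_vertex([0, 0, 0])})

    area = np.pi * p.diameter * L + 2 * np.pi * (p.diameter / 2) ** 2
    cm, g_na, g_k, g_l = p.cm * area, 1200.0 * area, 360.0 * area, p.leak_g * area
    e_na, e_k, e_l, inj = 0.050, -0.077, p.leak_erev, p.current

    def rhs(t, y):
        v, m, h, n = y
        vm = v * 1e3
        dv = (inj - g_l * (v - e_l) - g_na * m**3 * h * (v - e_na)
              - g_k * n**4 * (v - e_k)) / cm
        dm = rf.hh_alpha_m(vm) * (1 - m) - rf.hh_beta_m(vm) * m
        dh = rf.hh_alpha_h(vm) * (1 - h) - rf.hh_beta_h(vm) * h
        dn = rf.hh_alpha_n(vm) * (1 - n) - rf.hh_beta_n(vm) * n
        return [dv, dm, dh, dn]

    def inf(a, b):
        return a / (a + b)

    vm0 = e_l * 1e3
    y0 = [e_l,
          inf(rf.hh_alpha_m(vm0), rf.hh_beta_m(vm0)),
          inf(rf.hh_alpha_h(vm0), rf.hh_beta_h(vm0)),
          inf(rf.hh_alpha_n(vm0), rf.hh_beta_n(vm0))]
    sol = solve_ivp(rhs, [0, span], y0, t_eval=times, rtol=1e-10, atol=1e-12)
    return float(np.max(np.abs(rec["v"] - sol.y[0])))


def scaled_rallpack3_spikes(g_single: float = 1e-9, axial_segments: int = 16,
                            span: float = 0.025, seed: int = 7):
    """Scaled-down stochastic cable with HH channels; z_max spike features.

    Returns (peak heights V, peak times s, trace V).  The channel population
    is reduced by raising the single-channel conductance, keeping the total
    macroscopic conductance; the qualitative physiology (a propagated spike
    overshooting +40 mV) is preserved.
    """
    model, mesh, p = rallpack3_fixture(g_single=g_single,
                                       axial_segments=axial_segments)
    sim = Simulation(bind_model(model, mesh), Schedule(efield_dt=p.efield_dt),
                     seed=seed)
    z = mesh.vertices[:, 2]
    sim.add_injection(np.flatnonzero(np.isclose(z, 0.0)), p.current)
    record_dt = 5e-5
    times, rec = sim.run_record(span, record_dt,
                                {"zmax": sim.nearest_vertex([0, 0, p.length])})
    heights, stamps = detect_peaks(rec["zmax"], record_dt)
    return heights, stamps, rec["zmax"]


def reversible_outcomes(n_runs: int, seed: int, n_total: int = 100,
                        t_end: float = 0.3, feature: str = "mean_event_time"):
    """Scalar per-run outcomes of a reversible A<->B model.

    One small stochastic model run ``n_runs`` times with independent RNG
    streams spawned from ``seed``.  ``feature`` selects the outcome:
    ``mean_event_time`` (continuous and near-Gaussian by averaging over the
    run's ~45 events; the default for the CVM null experiment, where the
    heavy integer ties of a raw count would distort the asymptotic p-value
    tail) or ``end_count`` (the copy number of A at ``t_end``).
    """
    mesh = two_tet_mesh()
    model = Model(
        species=[Species("A"), Species("B")],
        compartments=[Compartment(
            name="comp",
            reactions=[Reaction({"A": 1}, {"B": 1}, 1.0),
                       Reaction({"B": 1}, {"A": 1}, 1.0)])],
    )
    bound = bind_model(model, mesh)
    procs = [kp for kp in bound.processes if kp.elem == 0]
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    out = np.empty(n_runs)
    for i, ss in enumerate(streams):
        M = MoleculeState(2, 2)
        M.vol[0, 0] = n_total
        K = KineticState(procs, M, np.random.default_rng(ss),
                         log_events=(feature == "mean_event_time"))
        K.initialize(0.0)
        K.run_window(0.0, t_end)
        if feature == "end_count":
            out[i] = M.vol[0, 0]
        elif feature == "mean_event_time":
            out[i] = (np.mean([e[0] for e in K.event_log])
                      if K.event_log else 0.0)
        else:
            raise ValueError(f"unknown feature {feature!r}")
    return out


def cvm_null_experiment(seed: int, n_runs: int = 10_000, batch_size: int = 100):
    """The same-model batched CVM comparison.

    Two independent sets of ``n_runs`` outcomes are drawn from one stochastic
    model, split into ``n_runs/batch_size`` batches and compared all-pairs.
    Returns (p-value matrix, median, fraction below 0.01).
    """
    a = reversible_outcomes(n_runs, seed * 2 + 1)
    b = reversible_outcomes(n_runs, seed * 2 + 2)
    p = cvm_batch_compare(a, b, batch_size)
    return p, float(np.median(p)), float((p < 0.01).mean())
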