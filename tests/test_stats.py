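"""Analytic cable oracle, peak detection, CVM batching, confidence bands."""

import numpy as np
import pytest
from scipy import stats as sps

from tetrd.fixtures import CableParams
from tetrd.stats import (TraceSet, ci_band, ci_band_compare,
                         cvm_batch_compare, cvm_reject, detect_peaks,
                         extract_peak_features, rallpack1_analytic)


def fd_cable_oracle(params, x_eval, t_eval, nx=2001, dt=2e-5):
    """Independent Crank-Nicolson finite-difference passive cable solver."""
    L, d = params.length, params.diameter
    r_m = 1.0 / (params.leak_g * np.pi * d)
    r_a = params.resistivity / (np.pi * (d / 2) ** 2)
    lam2 = r_m / r_a
    tau = params.cm / params.leak_g
    dx = L / (nx - 1)
    # tau dV/dt = lam2 V'' - V + r_m * i_inj(x); sealed (Neumann) ends
    main = np.full(nx, -2.0)
    main[0] = main[-1] = -2.0
    A = np.zeros((nx, nx))
    for i in range(nx):
        A[i, i] = -2.0
        if i > 0:
            A[i, i - 1] = 1.0
        if i < nx - 1:
            A[i, i + 1] = 1.0
    A[0, 1] = 2.0       # ghost-node reflection
    A[-1, -2] = 2.0
    Lop = lam2 / dx**2 * A - np.eye(nx)
    rhs = np.zeros(nx)
    # point injection enters the boundary node's half-width control cell
    rhs[0] = r_m * params.current / (dx / 2)
    I = np.eye(nx)
    M1 = I - dt / (2 * tau) * Lop
    M2 = I + dt / (2 * tau) * Lop
    M1inv = np.linalg.inv(M1)
    step = M1inv @ M2
    add = M1inv @ (dt / tau * rhs)
    # Rannacher startup: backward-Euler substeps damp the stiff modes the
    # step-on discontinuity excites (Crank-Nicolson alone leaves them ringing)
    be = np.linalg.inv(I - dt / tau * Lop)
    step_be = be
    add_be = be @ (dt / tau * rhs)
    v = np.zeros(nx)
    out = []
    targets = iter(sorted(t_eval))
    nxt = next(targets, None)
    t = 0.0
    nsteps = int(round(max(t_eval) / dt))
    xi = int(round(x_eval / dx))
    for k in range(nsteps + 1):
        if nxt is not None and t >= nxt - dt / 2:
            out.append(v[xi])
            nxt = next(targets, None)
        if k < 20:
            v = step_be @ v + add_be
        else:
            v = step @ v + add
        t += dt
    return np.asarray(out) + params.leak_erev


class TestCableOracle:
    def test_initial_condition(self):
        p = CableParams()
        assert rallpack1_analytic(p, 0.0, 0.0)[0] == pytest.approx(p.leak_erev)
        assert rallpack1_analytic(p, p.length / 2, 0.0)[0] == pytest.approx(
            p.leak_erev)

    def test_steady_state_cosh_profile(self):
        p = CableParams()
        lam = 1e-3  # sqrt(r_m / r_a) for these constants
        t = 10.0  # >> tau = 40 ms
        v1 = rallpack1_analytic(p, 0.2e-3, t)[0] - p.leak_erev
        v2 = rallpack1_analytic(p, 0.7e-3, t)[0] - p.leak_erev
        expect = np.cosh((p.length - 0.2e-3) / lam) / np.cosh(
            (p.length - 0.7e-3) / lam)
        assert v1 / v2 == pytest.approx(expect, rel=1e-9)

    def test_matches_finite_difference_oracle(self):
        # mid-transient times (tau = 40 ms): the FD scheme itself resolves
        # these to well under a microvolt at dx = 0.5 um, dt = 20 us
        p = CableParams()
        t_eval = [0.02, 0.05, 0.1]
        for x in (0.0, p.length):
            series = rallpack1_analytic(p, x, t_eval)
            fd = fd_cable_oracle(p, x, t_eval)
            assert np.max(np.abs(series - fd)) < 1e-6  # < 1 uV

    def test_monotone_rise_at_injection_end(self):
        p = CableParams()
        t = np.linspace(0.0, 0.25, 200)
        v = rallpack1_analytic(p, 0.0, t)
        assert np.all(np.diff(v) > -1e-12)
        assert v[0] == pytest.approx(p.leak_erev)

    def test_out_of_domain_rejected(self):
        p = CableParams()
        with pytest.raises(ValueError):
            rallpack1_analytic(p, -1e-6, 0.1)
        with pytest.raises(ValueError):
            rallpack1_analytic(p, 0.0, [-0.1])


class TestPeaks:
    def test_constant_trace_no_peaks(self):
        h, t = detect_peaks(np.full(1000, -0.065), dt=1e-4)
        assert len(h) == 0 and len(t) == 0

    def test_sinusoid_frequency(self):
        dt = 1e-4
        t = np.arange(0, 1.0, dt)
        trace = 0.05 * np.sin(2 * np.pi * 10 * t)
        h, ts = detect_peaks(trace, dt)
        freq = (len(ts) - 1) / (ts[-1] - ts[0])
        assert freq == pytest.approx(10.0, rel=1e-3)

    def test_gaussian_bumps_timestamps(self):
        dt = 1e-4
        t = np.arange(0, 0.1, dt)
        trace = (0.08 * np.exp(-((t - 0.03) / 0.002) ** 2)
                 + 0.06 * np.exp(-((t - 0.07) / 0.002) ** 2) - 0.065)
        h, ts = detect_peaks(trace, dt)
        assert len(ts) == 2
        assert abs(ts[0] - 0.03) <= dt and abs(ts[1] - 0.07) <= dt

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        trace = np.cumsum(rng.normal(size=500)) * 1e-3
        h1, t1 = detect_peaks(trace, 1e-4)
        h2, t2 = detect_peaks(trace + 0.5, 1e-4)
        assert np.array_equal(t1, t2)
        assert np.allclose(h2 - h1, 0.5)

    def test_feature_extraction_per_run(self):
        dt = 1e-4
        t = np.arange(0, 0.1, dt)
        rows = [0.08 * np.exp(-((t - c) / 0.002) ** 2) for c in (0.03, 0.05)]
        feats = extract_peak_features(TraceSet(dt, np.vstack(rows)))
        assert [len(x) for x in feats.heights] == [1, 1]
        assert feats.timestamps[0][0] == pytest.approx(0.03, abs=dt)


class TestCvm:
    def test_null_all_pairs_near_uniform(self, rng):
        a = rng.normal(size=2500)
        b = rng.normal(size=2500)
        p = cvm_batch_compare(a, b, batch_size=50)
        assert p.shape == (50, 50)
        # batch reuse correlates the all-pairs p-values, so allow a wider
        # band than the independent-pair binomial one
        assert (p < 0.01).mean() < 0.025
        assert abs(np.median(p) - 0.5) < 0.1

    def test_null_independent_pairs_uniform(self):
        # disjoint batch pairs give independent p-values: the empirical CDF
        # must be uniform to Kolmogorov distance < 0.02 at 1e4 p-values
        rng = np.random.default_rng(123)
        ps = np.array([
            sps.cramervonmises_2samp(rng.normal(size=50),
                                     rng.normal(size=50)).pvalue
            for _ in range(10_000)
        ])
        ks = np.max(np.abs(np.sort(ps) - (np.arange(1, 10_001) - 0.5) / 10_000))
        assert ks < 0.02
        assert abs((ps < 0.01).mean() - 0.01) < 3 * np.sqrt(0.0099 / 10_000)

    def test_power_against_mean_shift(self, rng):
        a = rng.normal(size=2000)
        b = rng.normal(loc=1.0, size=2000)  # shift = 1 sd
        p = cvm_batch_compare(a, b, batch_size=100)
        assert (p < 0.01).mean() > 0.99
        reject, _ = cvm_reject(p)
        assert reject

    def test_small_batches_use_exact_method(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        p = cvm_batch_compare(a, b, batch_size=10)
        assert p.shape == (4, 4)
        assert ((0 <= p) & (p <= 1)).all()

    def test_batch_size_exceeding_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            cvm_batch_compare(rng.normal(size=50), rng.normal(size=50), 100)


class TestCiBand:
    def test_identical_constant_traces(self):
        ts = TraceSet(1e-3, np.full((5, 20), 3.14))
        mean, lo, hi = ci_band(ts)
        assert np.allclose(mean, 3.14) and np.allclose(lo, hi)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            ci_band(TraceSet(1e-3, np.zeros((1, 10))))

    def test_coverage_near_nominal(self, rng):
        # true mean inside the 99% band at ~99% of time points
        hits = []
        for _ in range(50):
            ts = TraceSet(1e-3, rng.normal(loc=1.0, size=(30, 40)))
            _, lo, hi = ci_band(ts, 0.99)
            hits.append(((lo <= 1.0) & (1.0 <= hi)).mean())
        assert 0.97 < np.mean(hits) <= 1.0

    def test_self_consistency_accepts(self, rng):
        accept = 0
        trials = 40
        for _ in range(trials):
            a = TraceSet(1e-3, rng.normal(size=(50, 30)))
            b = TraceSet(1e-3, rng.normal(size=(50, 30)))
            reject, _ = ci_band_compare(a, b)
            accept += not reject
        assert accept / trials >= 0.95

    def test_detects_offset(self, rng):
        a = TraceSet(1e-3, rng.normal(size=(50, 30)))
        b = TraceSet(1e-3, rng.normal(loc=2.0, size=(50, 30)))
        reject, frac = ci_band_compare(a, b)
        assert reject and frac > 0.9
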