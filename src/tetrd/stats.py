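"""Validation statistics: analytic passive cable, spike features, batched
Cramér-von Mises comparison and confidence-band comparison.

The passive-cable oracle solves the cable equation on a sealed cylinder of
length L with a step current I injected at x = 0 at t = 0:

    V(x, t) = E + V_ss(x) - sum_n a_n cos(n pi x / L) exp(-t / tau_n)

with space constant lambda = sqrt(r_m / r_a), membrane time constant
tau = c_m r_m = Cm / g_leak, steady state
``V_ss = I r_a lambda cosh((L-x)/lambda) / sinh(L/lambda)``, eigenmode time
constants ``tau_n = tau / (1 + (n pi lambda / L)^2)`` and cosine coefficients
``a_n = (2 - delta_n0) I r_a lambda^2 / (L (1 + (n pi lambda / L)^2))``
(the cosine-series expansion of V_ss, so V(x, 0) = E exactly).

Stochastic-simulator comparisons follow a batched two-sample scheme: both
sample sets are split into batches, every batch of one set is CVM-tested
against every batch of the other, and the null is rejected only when the
fraction of p-values below 0.01 is significantly above the 1% expected under
uniformity.  Smooth traces are compared through pointwise Student-t
confidence bands instead: reject when one set's mean trace leaves the other
set's band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy import stats as sps


@dataclass
class TraceSet:
    """Uniformly sampled traces from repeated runs (runs x time points)."""

    dt: float
    data: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.dt <= 0:
            raise ValueError("sampling step must be positive")

    @property
    def num_runs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.dt


@dataclass
class PeakFeatures:
    """Per-run spike features."""

    heights: list[np.ndarray]     # V
    timestamps: list[np.ndarray]  # s

    def frequency(self, run: int = 0) -> float:
        t = self.timestamps[run]
        if len(t) < 2:
            return 0.0
        return (len(t) - 1) / (t[-1] - t[0])


# ---------------------------------------------------------------------------
# passive cable oracle

def rallpack1_analytic(params, x, t, tol: float = 1e-9) -> np.ndarray:
    """Membrane potential (V) of the passive-cable benchmark at position x.

    ``params`` needs attributes length, diameter, leak_g, leak_erev,
    resistivity, cm, current (SI units).  ``t`` may be an array.
    """
    L, d = params.length, params.diameter
    if not 0 <= x <= L:
        raise ValueError("x outside the cable")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    r_m = 1.0 / (params.leak_g * np.pi * d)          # Ohm m
    r_a = params.resistivity / (np.pi * (d / 2) ** 2)  # Ohm / m
    lam = np.sqrt(r_m / r_a)
    tau = params.cm / params.leak_g
    I = params.current

    v_ss = I * r_a * lam * np.cosh((L - x) / lam) / np.sinh(L / lam)
    out = np.full(t.shape, v_ss)

    # transient cosine series, truncated when the remaining amplitude at the
    # smallest positive requested time is below tol
    t_pos = t[t > 0]
    t_min = t_pos.min() if len(t_pos) else None
    n = 0
    while True:
        mu = 1.0 + (n * np.pi * lam / L) ** 2
        a_n = (1.0 if n == 0 else 2.0) * I * r_a * lam**2 / (L * mu)
        term = a_n * np.cos(n * np.pi * x / L) * np.exp(-t * mu / tau)
        out -= np.where(t > 0, term, 0.0)
        # amplitude bound of everything beyond n at t_min
        if t_min is not None:
            bound = 2 * I * r_a * lam**2 / (L * (1 + ((n + 1) * np.pi * lam / L) ** 2)) \
                * np.exp(-t_min * (1 + ((n + 1) * np.pi * lam / L) ** 2) / tau)
            # geometric-ish tail: multiply by a slack factor for the 1/n^2 sum
            bound *= n + 10
        else:
            bound = 0.0
        n += 1
        if t_min is None or bound < tol:
            break
        if n > 200000:
            raise RuntimeError(
                f"cable series did not reach tolerance {tol}; bound {bound:.3e}")
    out[t == 0] = 0.0
    return out + params.leak_erev


# ---------------------------------------------------------------------------
# spike features

def detect_peaks(trace: np.ndarray, dt: float, min_prominence: float = 0.010,
                 min_separation: float = 0.002) -> tuple[np.ndarray, np.ndarray]:
    """Peak (heights, timestamps) of one uniformly sampled trace.

    Defaults suit HH spike trains: 10 mV prominence, 2 ms separation.
    """
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = signal.find_peaks(np.asarray(trace, float),
                               prominence=min_prominence, distance=distance)
    return np.asarray(trace, float)[idx], idx * dt


def extract_peak_features(traces: TraceSet, min_prominence: float = 0.010,
                          min_separation: float = 0.002) -> PeakFeatures:
    heights, stamps = [], []
    for row in traces.data:
        h, ts = detect_peaks(row, traces.dt, min_prominence, min_separation)
        heights.append(h)
        stamps.append(ts)
    return PeakFeatures(heights, stamps)


# ---------------------------------------------------------------------------
# batched CVM comparison

def cvm_batch_compare(samples_a, samples_b, batch_size: int = 100,
                      method: str | None = None) -> np.ndarray:
    """All-pairs two-sample Cramér-von Mises p-values over equal batches.

    Both samples are split into ``len(sample)//batch_size`` consecutive
    batches; every batch of A is tested against every batch of B.  With 100
    batches a side this yields a 100 x 100 matrix of p-values, uniform on
    [0, 1] under the null.  Batches smaller than 20 use the exact permutation
    distribution, larger ones the asymptotic one.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if len(a) < batch_size or len(b) < batch_size:
        raise ValueError("batch size exceeds sample size")
    na, nb = len(a) // batch_size, len(b) // batch_size
    if method is None:
        method = "exact" if batch_size < 20 else "asymptotic"
    batches_a = a[: na * batch_size].reshape(na, batch_size)
    batches_b = b[: nb * batch_size].reshape(nb, batch_size)
    out = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            out[i, j] = sps.cramervonmises_2samp(
                batches_a[i], batches_b[j], method=method).pvalue
    return out


def cvm_reject(pvalues: np.ndarray, level: float = 0.01,
               sigmas: float = 3.0) -> tuple[bool, float]:
    """The consistently-low-p rejection rule.

    Under the null a fraction ``level`` of p-values falls below ``level``;
    reject only when the observed fraction exceeds that by more than
    ``sigmas`` binomial standard deviations.  Returns (reject, fraction).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    frac = float((p < level).mean())
    thresh = level + sigmas * np.sqrt(level * (1 - level) / len(p))
    return frac > thresh, frac


# ---------------------------------------------------------------------------
# confidence bands

def ci_band(traces: TraceSet, level: float = 0.99):
    """Pointwise mean and Student-t confidence band of the mean trace."""
    n = traces.num_runs
    if n < 2:
        raise ValueError("confidence bands need at least 2 runs")
    mean = traces.data.mean(axis=0)
    sd = traces.data.std(axis=0, ddof=1)
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return mean, mean - half, mean + half


def ci_band_compare(a: TraceSet, b: TraceSet, level: float = 0.99,
                    frac_tol: float = 0.05):
    """Mean-in-band verdict on two trace sets.

    The containment band accounts for the sampling noise of *both* means
    (pointwise two-sample Student band at ``level``): comparing one mean
    against the other set's plain one-sample band rejects independent
    replicates of the same model far too often, because the compared mean
    carries the same order of noise as the band half-width.  A mean "almost
    always" inside the band passes: up to ``frac_tol`` of time points may
    stray (pointwise bands give no simultaneous coverage).  Returns
    (reject, fraction of points outside).
    """
    na, nb = a.num_runs, b.num_runs
    if na < 2 or nb < 2:
        raise ValueError("confidence-band comparison needs >= 2 runs per set")
    mean_a = a.data.mean(axis=0)
    mean_b = b.data.mean(axis=0)
    var_a = a.data.var(axis=0, ddof=1) / na
    var_b = b.data.var(axis=0, ddof=1) / nb
    half = sps.t.ppf(0.5 + level / 2.0, min(na, nb) - 1) * np.sqrt(var_a + var_b)
    outside = float((np.abs(mean_a - mean_b) > half).mean())
    return outside > frac_tol, outside
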