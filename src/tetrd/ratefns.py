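"""Named voltage-dependent rate functions (s^-1, V in mV).

The Hodgkin-Huxley squid-axon alpha/beta forms, written for a resting
potential of -65 mV.  The textbook expressions are per millisecond; these
return per second.  Removable singularities (alpha_n at -55 mV, alpha_m at
-40 mV) are evaluated by the x/(1-e^-x) -> 1 limit.
"""

from __future__ import annotations

import numpy as np


def _x_over_expm1(x):
    """x / (1 - exp(-x)), finite at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-9, 1.0 + x / 2.0, x / (-np.expm1(-np.where(np.abs(x) < 1e-9, 1.0, x))))
    return out


def hh_alpha_n(v_mV):
    return 1e3 * 0.1 * _x_over_expm1((np.asarray(v_mV, float) + 55.0) / 10.0)


def hh_beta_n(v_mV):
    return 1e3 * 0.125 * np.exp(-(np.asarray(v_mV, float) + 65.0) / 80.0)


def hh_alpha_m(v_mV):
    return 1e3 * _x_over_expm1((np.asarray(v_mV, float) + 40.0) / 10.0)


def hh_beta_m(v_mV):
    return 1e3 * 4.0 * np.exp(-(np.asarray(v_mV, float) + 65.0) / 18.0)


def hh_alpha_h(v_mV):
    return 1e3 * 0.07 * np.exp(-(np.asarray(v_mV, float) + 65.0) / 20.0)


def hh_beta_h(v_mV):
    return 1e3 * 1.0 / (1.0 + np.exp(-(np.asarray(v_mV, float) + 35.0) / 10.0))


BUILTINS = {
    "hh_alpha_n": hh_alpha_n,
    "hh_beta_n": hh_beta_n,
    "hh_alpha_m": hh_alpha_m,
    "hh_beta_m": hh_beta_m,
    "hh_alpha_h": hh_alpha_h,
    "hh_beta_h": hh_beta_h,
}
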