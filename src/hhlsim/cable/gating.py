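"""Hodgkin-Huxley gating kinetics of the SGN axonal Na and K channels.

Rate functions are in 1/ms with voltage in mV, valid at body
temperature (no extra Q10 scaling).  The linoid forms have removable
singularities that are evaluated by their limits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rates", "steady_state", "linoid"]


def linoid(x, s):
    """x / (1 - exp(-x/s)), with the limit value s at x = 0."""
    x = np.asarray(x, dtype=float)
    u = x / s
    small = np.abs(u) < 1e-7
    u_safe = np.where(small, 1.0, u)
    out = np.where(small, s * (1.0 + u / 2.0), x / -np.expm1(-u_safe))
    if out.ndim == 0:
        return float(out)
    return out


def rates(v):
    """Opening/closing rates (1/ms) of m, h, n at membrane voltage v (mV).

    Returns
    -------
    (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)
    """
    v = np.asarray(v, dtype=float)
    a_m = 1.872 * linoid(v + 52.59, 6.06)
    b_m = -3.973 * linoid(v + 57.0, -9.41)
    a_h = -0.549 * linoid(v + 105.74, -9.06)
    b_h = 22.57 / (1.0 + np.exp(-(v + 22.0) / 12.5))
    a_n = 0.129 * linoid(v + 43.0, 10.0)
    b_n = -0.324 * linoid(v + 68.0, -10.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def steady_state(v):
    """Steady-state activation (m_inf, h_inf, n_inf) at voltage v (mV)."""
    a_m, b_m, a_h, b_h, a_n, b_n = rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)
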