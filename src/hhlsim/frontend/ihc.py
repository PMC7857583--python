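"""Inner-hair-cell transduction: BM velocity -> vesicle release rate.

The chain is, per channel and fiber type:

1. cilia displacement u(t): first-order lag of BM velocity,
   tau_c du/dt + u = tau_c * C_cilia * v(t);
2. apical conductance G(u): three-state Boltzmann between G_a and
   G_a + G_cilia_max;
3. IHC membrane potential V(t): C_m dV/dt + G(u)(V - E_t)
   + G_k (V - E_k') = 0 with E_k' = E_k + E_t R_p / (R_p + R_t);
4. calcium activation m(t): first-order relaxation to a logistic
   m_inf(V) with time constant tau_m;
5. calcium current magnitude I_Ca = G_Ca_max m^3 (E_Ca - V);
6. near-synapse calcium concentration: d[Ca]/dt = I_Ca - [Ca]/tau_Ca;
7. per-vesicle release rate k(t) = max(([Ca]^3 - thr^3) z, 0).

Internal units: nm for u, mV for potentials, nS for conductances; the
calcium concentration is kept in the model's own consistent units
(I_Ca * tau) and only ever compared against the same-unit threshold.
Steps 1-6 are integrated by an explicit first-order update on the
shared simulation grid (5 us default), which resolves the fastest time
constant (0.1 ms) by a factor 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class IHCParams:
    """Transduction constants shared by all fiber types."""

    tau_c_ms: float = 2.13
    cilia_gain: float = 1.0        # C_cilia: nm per (BM velocity unit) per ms
    g_cilia_max_nS: float = 8.0
    g_a_nS: float = 0.33
    u0_nm: float = 7.0
    s0_nm: float = 85.0
    u1_nm: float = 7.0
    s1_nm: float = 5.0
    c_m_pF: float = 6.0
    g_k_nS: float = 27.1
    e_t_mV: float = 100.0
    e_k_mV: float = -70.45
    rp_over_rp_rt: float = 0.04
    tau_m_ca_ms: float = 0.1
    beta_ca: float = 400.0
    gamma_ca_per_mV: float = 0.13
    e_ca_mV: float = 66.0
    tau_ca_ms: float = 0.1

    @property
    def e_k_prime_mV(self) -> float:
        return self.e_k_mV + self.e_t_mV * self.rp_over_rp_rt


def apical_conductance(u_nm, p: IHCParams):
    """Boltzmann apical conductance G(u) in nS."""
    u = np.asarray(u_nm, dtype=float)
    g = p.g_cilia_max_nS / (
        (1.0 + np.exp(-(u - p.u0_nm) / p.s0_nm))
        * (1.0 + np.exp(-(u - p.u1_nm) / p.s1_nm))
    )
    out = g + p.g_a_nS
    return float(out) if out.ndim == 0 else out


def resting_state(p: IHCParams, g_ca_max_nS: float):
    """Algebraic rest point (u=0): V, m, [Ca] with no BM input."""
    g0 = apical_conductance(0.0, p)
    v = (g0 * p.e_t_mV + p.g_k_nS * p.e_k_prime_mV) / (g0 + p.g_k_nS)
    m = 1.0 / (1.0 + np.exp(-p.gamma_ca_per_mV * v) / p.beta_ca)
    i_ca = g_ca_max_nS * m**3 * (p.e_ca_mV - v)
    ca = i_ca * p.tau_ca_ms
    return v, m, ca


@njit(cache=True)
def _ihc_kernel(
    v_bm, dt,
    tau_c, cilia_gain,
    g_max, g_a, u0, s0, u1, s1,
    c_m_pF, g_k, e_t, e_kp,
    tau_m, beta, gamma, e_ca, tau_ca,
    g_ca_max,
    v0, m0, ca0,
    ca_out,
):
    u = 0.0
    v = v0
    m = m0
    ca = ca0
    n = v_bm.size
    c_m = c_m_pF  # nS*mV = pA and pA/pF = mV/ms, so pF is already consistent
    for i in range(n):
        # cilia lag — explicit Euler
        u += dt * (cilia_gain * v_bm[i] - u / tau_c)
        # Boltzmann apical conductance
        g = g_max / (
            (1.0 + np.exp(-(u - u0) / s0)) * (1.0 + np.exp(-(u - u1) / s1))
        ) + g_a
        # IHC membrane potential
        v += dt * (-(g * (v - e_t) + g_k * (v - e_kp)) / c_m)
        # calcium activation
        m_inf = 1.0 / (1.0 + np.exp(-gamma * v) / beta)
        m += dt * (m_inf - m) / tau_m
        # calcium current magnitude and concentration
        i_ca = g_ca_max * m * m * m * (e_ca - v)
        ca += dt * (i_ca - ca / tau_ca)
        ca_out[i] = ca
    return 0


def ihc_transduction(
    v_bm: np.ndarray,
    dt_ms: float,
    params: IHCParams,
    g_ca_max_nS: float,
) -> np.ndarray:
    """Integrate the IHC chain; returns the [Ca](t) trajectory.

    The state starts at the algebraic rest point, so a silent input
    yields a constant resting calcium level.
    """
    v0, m0, ca0 = resting_state(params, g_ca_max_nS)
    ca = np.empty(v_bm.size)
    p = params
    _ihc_kernel(
        np.ascontiguousarray(v_bm, dtype=np.float64), dt_ms,
        p.tau_c_ms, p.cilia_gain,
        p.g_cilia_max_nS, p.g_a_nS, p.u0_nm, p.s0_nm, p.u1_nm, p.s1_nm,
        p.c_m_pF, p.g_k_nS, p.e_t_mV, p.e_k_prime_mV,
        p.tau_m_ca_ms, p.beta_ca, p.gamma_ca_per_mV, p.e_ca_mV, p.tau_ca_ms,
        g_ca_max_nS,
        v0, m0, ca0,
        ca,
    )
    return ca


def release_rate(ca: np.ndarray, ca_thr: float, z: float) -> np.ndarray:
    """Per-vesicle release rate k(t) in 1/s from the calcium trajectory."""
    ca = np.asarray(ca, dtype=float)
    k = (ca**3 - ca_thr**3) * z
    return np.maximum(k, 0.0)
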