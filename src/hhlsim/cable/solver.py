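"""Implicit cable solver (backward Euler in time, tridiagonal in space).

The transmembrane voltage is advanced fully implicitly: each step the
gating variables are first updated over the sub-interval by their exact
exponential (Rush-Larsen) solution at the current voltage, then the
ionic and synaptic currents are linearized about the new gating state,
which makes the spatial system linear and tridiagonal in the unknown
voltages.  The tridiagonal system is solved by the Thomas algorithm.

Units: mV, ms, nF, uS, nA.  Synaptic drive is the double-exponential
conductance of a vesicle-release event with reversal ``e_syn``;
superposition over releases is handled with two running exponential
state variables, so an arbitrary release train costs O(1) per step.

All kernels are numba-compiled; they operate on flat arrays so that a
whole fiber population can be run in one call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_SPIKES = 64


@njit(cache=True, inline="always")
def _linoid(x, s):
    u = x / s
    if abs(u) < 1e-7:
        return s * (1.0 + 0.5 * u)
    return x / -np.expm1(-u)


@njit(cache=True, inline="always")
def _rates(v):
    a_m = 1.872 * _linoid(v + 52.59, 6.06)
    b_m = -3.973 * _linoid(v + 57.0, -9.41)
    a_h = -0.549 * _linoid(v + 105.74, -9.06)
    b_h = 22.57 / (1.0 + np.exp(-(v + 22.0) / 12.5))
    a_n = 0.129 * _linoid(v + 43.0, 10.0)
    b_n = -0.324 * _linoid(v + 68.0, -10.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True)
def run_fiber(
    v, m, h, n,                      # state, modified in place (n_comp,)
    c_nF, g_leak, g_na, g_k, g_ax,   # grid arrays (uS / nF)
    e_na, e_k, e_rest,
    dt, n_steps, settle_steps,
    rel_steps,                       # sorted global step indices of releases
    g_syn_peak_uS, tau1, tau2, e_syn, syn_comp,
    detect_comp, thresh, dead_ms,
    spike_times,                     # out buffer (MAX_SPIKES,)
    record_idx, record_out,          # (n_rec,), (n_rec, n_steps+1); n_rec may be 0
):
    """Advance one fiber ``n_steps`` steps; return the number of spikes.

    Spike times are upward crossings of ``thresh`` at ``detect_comp``
    (linearly interpolated within the step) with a ``dead_ms`` dead
    time, reported in ms relative to the end of the settling period.
    """
    nc = v.size
    a = np.empty(nc)
    b = np.empty(nc)
    rhs = np.empty(nc)
    cp = np.empty(nc)

    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)
    # normalization so that the peak of (s2 - s1) per release equals 1
    tpk = np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)
    peak = np.exp(-tpk / tau2) - np.exp(-tpk / tau1)
    s1 = 0.0
    s2 = 0.0

    n_rec = record_idx.size
    for r in range(n_rec):
        record_out[r, 0] = v[record_idx[r]]

    n_spk = 0
    last_spike = -1e9
    i_rel = 0
    n_rel = rel_steps.size

    for step in range(n_steps):
        # synaptic conductance state: releases fire at the step start
        while i_rel < n_rel and rel_steps[i_rel] == step:
            s1 += 1.0
            s2 += 1.0
            i_rel += 1
        s1 *= d1
        s2 *= d2
        g_syn = g_syn_peak_uS * (s2 - s1) / peak

        v_old_det = v[detect_comp]

        # gating: exact exponential update at the pre-step voltage
        for i in range(nc):
            if g_na[i] > 0.0 or g_k[i] > 0.0:
                a_m, b_m, a_h, b_h, a_n, b_n = _rates(v[i])
                tm = a_m + b_m
                m[i] = a_m / tm + (m[i] - a_m / tm) * np.exp(-dt * tm)
                th_ = a_h + b_h
                h[i] = a_h / th_ + (h[i] - a_h / th_) * np.exp(-dt * th_)
                tn = a_n + b_n
                n[i] = a_n / tn + (n[i] - a_n / tn) * np.exp(-dt * tn)

        # assemble the tridiagonal system for the implicit voltage solve
        for i in range(nc):
            g_ion = g_leak[i]
            e_drive = g_leak[i] * e_rest
            if g_na[i] > 0.0:
                gna_eff = g_na[i] * m[i] * m[i] * m[i] * h[i]
                g_ion += gna_eff
                e_drive += gna_eff * e_na
            if g_k[i] > 0.0:
                gk_eff = g_k[i] * n[i] * n[i] * n[i] * n[i]
                g_ion += gk_eff
                e_drive += gk_eff * e_k
            if i == syn_comp and g_syn != 0.0:
                g_ion += g_syn
                e_drive += g_syn * e_syn
            diag = c_nF[i] / dt + g_ion
            if i > 0:
                diag += g_ax[i - 1]
            if i < nc - 1:
                diag += g_ax[i]
            a[i] = diag
            rhs[i] = c_nF[i] / dt * v[i] + e_drive

        # Thomas algorithm (sub/super diagonal = -g_ax)
        cp[0] = -g_ax[0] / a[0]
        b[0] = rhs[0] / a[0]
        for i in range(1, nc):
            denom = a[i] + g_ax[i - 1] * cp[i - 1]
            if i < nc - 1:
                cp[i] = -g_ax[i] / denom
            b[i] = (rhs[i] + g_ax[i - 1] * b[i - 1]) / denom
        v[nc - 1] = b[nc - 1]
        for i in range(nc - 2, -1, -1):
            v[i] = b[i] - cp[i] * v[i + 1]

        for r in range(n_rec):
            record_out[r, step + 1] = v[record_idx[r]]

        # spike detection at the heminode center
        t_now = (step + 1 - settle_steps) * dt
        v_new_det = v[detect_comp]
        if (
            v_old_det < thresh <= v_new_det
            and t_now - last_spike >= dead_ms
            and n_spk < MAX_SPIKES
        ):
            frac = (thresh - v_old_det) / (v_new_det - v_old_det)
            t_spike = t_now - dt + frac * dt
            spike_times[n_spk] = t_spike
            n_spk += 1
            last_spike = t_spike

    return n_spk


V_TAB_MIN = -150.0
V_TAB_MAX = 80.0
V_TAB_STEP = 0.05


_TAB_CACHE: dict = {}


def build_gating_tables(dt: float) -> np.ndarray:
    """Tabulate (x_inf, exp(-dt (alpha+beta))) for m, h, n on a voltage
    grid, for the population fast path (linear interpolation; the
    0.05 mV grid keeps the interpolation error far below the solver's
    own discretization error)."""
    if dt in _TAB_CACHE:
        return _TAB_CACHE[dt]
    v = np.arange(V_TAB_MIN, V_TAB_MAX + V_TAB_STEP / 2, V_TAB_STEP)
    tab = np.empty((v.size, 6))
    for col, (ia, ib) in enumerate(((0, 1), (2, 3), (4, 5))):
        a = np.empty_like(v)
        b = np.empty_like(v)
        for k in range(v.size):
            r = _rates(v[k])
            a[k] = r[ia]
            b[k] = r[ib]
        tab[:, 2 * col] = a / (a + b)
        tab[:, 2 * col + 1] = np.exp(-dt * (a + b))
    _TAB_CACHE[dt] = tab
    return tab


@njit(cache=True)
def run_fiber_tab(
    v, m, h, n,
    c_nF, g_leak, g_na, g_k, g_ax,
    e_na, e_k, e_rest,
    dt, n_steps, settle_steps,
    rel_steps,
    g_syn_peak_uS, tau1, tau2, e_syn, syn_comp,
    detect_comp, thresh, dead_ms,
    spike_times,
    gating_tab,
):
    """Population fast path of :func:`run_fiber`: identical scheme,
    gating steady states and decay factors interpolated from a
    precomputed voltage table instead of evaluated per step."""
    nc = v.size
    a = np.empty(nc)
    b = np.empty(nc)
    rhs = np.empty(nc)
    cp = np.empty(nc)

    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)
    tpk = np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)
    peak = np.exp(-tpk / tau2) - np.exp(-tpk / tau1)
    s1 = 0.0
    s2 = 0.0

    inv_step = 1.0 / V_TAB_STEP
    n_tab = gating_tab.shape[0]

    n_spk = 0
    last_spike = -1e9
    i_rel = 0
    n_rel = rel_steps.size

    for step in range(n_steps):
        while i_rel < n_rel and rel_steps[i_rel] == step:
            s1 += 1.0
            s2 += 1.0
            i_rel += 1
        s1 *= d1
        s2 *= d2
        g_syn = g_syn_peak_uS * (s2 - s1) / peak

        v_old_det = v[detect_comp]

        for i in range(nc):
            if g_na[i] > 0.0 or g_k[i] > 0.0:
                u = (v[i] - V_TAB_MIN) * inv_step
                j = int(u)
                if j < 0:
                    j = 0
                elif j > n_tab - 2:
                    j = n_tab - 2
                frac = u - j
                m_inf = gating_tab[j, 0] + frac * (
                    gating_tab[j + 1, 0] - gating_tab[j, 0]
                )
                dm = gating_tab[j, 1] + frac * (
                    gating_tab[j + 1, 1] - gating_tab[j, 1]
                )
                h_inf = gating_tab[j, 2] + frac * (
                    gating_tab[j + 1, 2] - gating_tab[j, 2]
                )
                dh = gating_tab[j, 3] + frac * (
                    gating_tab[j + 1, 3] - gating_tab[j, 3]
                )
                n_inf = gating_tab[j, 4] + frac * (
                    gating_tab[j + 1, 4] - gating_tab[j, 4]
                )
                dn = gating_tab[j, 5] + frac * (
                    gating_tab[j + 1, 5] - gating_tab[j, 5]
                )
                m[i] = m_inf + (m[i] - m_inf) * dm
                h[i] = h_inf + (h[i] - h_inf) * dh
                n[i] = n_inf + (n[i] - n_inf) * dn

        for i in range(nc):
            g_ion = g_leak[i]
            e_drive = g_leak[i] * e_rest
            if g_na[i] > 0.0:
                gna_eff = g_na[i] * m[i] * m[i] * m[i] * h[i]
                g_ion += gna_eff
                e_drive += gna_eff * e_na
            if g_k[i] > 0.0:
                gk_eff = g_k[i] * n[i] * n[i] * n[i] * n[i]
                g_ion += gk_eff
                e_drive += gk_eff * e_k
            if i == syn_comp and g_syn != 0.0:
                g_ion += g_syn
                e_drive += g_syn * e_syn
            diag = c_nF[i] / dt + g_ion
            if i > 0:
                diag += g_ax[i - 1]
            if i < nc - 1:
                diag += g_ax[i]
            a[i] = diag
            rhs[i] = c_nF[i] / dt * v[i] + e_drive

        cp[0] = -g_ax[0] / a[0]
        b[0] = rhs[0] / a[0]
        for i in range(1, nc):
            denom = a[i] + g_ax[i - 1] * cp[i - 1]
            if i < nc - 1:
                cp[i] = -g_ax[i] / denom
            b[i] = (rhs[i] + g_ax[i - 1] * b[i - 1]) / denom
        v[nc - 1] = b[nc - 1]
        for i in range(nc - 2, -1, -1):
            v[i] = b[i] - cp[i] * v[i + 1]

        t_now = (step + 1 - settle_steps) * dt
        v_new_det = v[detect_comp]
        if (
            v_old_det < thresh <= v_new_det
            and t_now - last_spike >= dead_ms
            and n_spk < MAX_SPIKES
        ):
            frac = (thresh - v_old_det) / (v_new_det - v_old_det)
            t_spike = t_now - dt + frac * dt
            spike_times[n_spk] = t_spike
            n_spk += 1
            last_spike = t_spike

    return n_spk


@njit(cache=True)
def run_population(
    comp_off,                         # (F+1,) offsets into flat comp arrays
    c_nF, g_leak, g_na, g_k,          # flat (sum n_comp,)
    g_ax, ax_off,                     # flat (sum n_comp-1,), offsets (F+1,)
    detect_comp,                      # (F,) local index per fiber
    e_na, e_k, e_rest,
    m0, h0, n0,
    dt, n_steps, settle_steps,
    rel_flat, rel_off,                # release times (ms, >=0), per fiber
    g_syn_peak_uS, tau1, tau2, e_syn,
    thresh, dead_ms,
    spikes_out, n_spk_out,            # (F, MAX_SPIKES), (F,)
    gating_tab,
):
    """Run every fiber of a population serially (tabulated fast path)."""
    n_fibers = comp_off.size - 1
    for f in range(n_fibers):
        lo = comp_off[f]
        hi = comp_off[f + 1]
        nc = hi - lo
        v = np.full(nc, e_rest)
        m = np.full(nc, m0)
        h = np.full(nc, h0)
        n = np.full(nc, n0)
        rl = rel_flat[rel_off[f]:rel_off[f + 1]]
        rel_steps = np.empty(rl.size, dtype=np.int64)
        for k in range(rl.size):
            rel_steps[k] = settle_steps + int(np.rint(rl[k] / dt))
        n_spk_out[f] = run_fiber_tab(
            v, m, h, n,
            c_nF[lo:hi], g_leak[lo:hi], g_na[lo:hi], g_k[lo:hi],
            g_ax[ax_off[f]:ax_off[f + 1]],
            e_na, e_k, e_rest,
            dt, n_steps, settle_steps,
            rel_steps,
            g_syn_peak_uS, tau1, tau2, e_syn, 0,
            detect_comp[f], thresh, dead_ms,
            spikes_out[f],
            gating_tab,
        )
    return 0
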