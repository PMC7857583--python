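"""Numerical validation of the implicit cable solver."""

import numpy as np
import pytest
from scipy.linalg import expm

from hhlsim.cable import (
    FiberMorphology,
    MembraneParams,
    SynapticPulse,
    build_cable,
    simulate_fiber,
    steady_state,
)
from hhlsim.cable.solver import run_fiber


def _passive_params():
    return MembraneParams(
        g_na_node=0.0, g_k_node=0.0, g_na_unmyel=0.0, g_k_unmyel=0.0
    )


def test_rest_is_stable_for_10_ms(control_grid):
    sp, t, v = simulate_fiber(
        control_grid, [], 10.0, record=(control_grid.idx_heminode,)
    )
    assert sp.size == 0
    assert np.abs(v[0] + 78.0).max() < 1.0


def test_backward_euler_matches_matrix_exponential_oracle():
    """A 3-compartment passive cable advanced one implicit step agrees
    with the dense matrix-exponential solution to 0.1%."""
    c = np.array([1.0, 2.0, 1.5])          # nF
    gl = np.array([0.5, 0.4, 0.6])         # uS
    gax = np.array([2.0, 3.0])
    e_rest = -78.0
    # dV/dt = A (V - e_rest) with A = C^-1 (coupling - leak)
    lap = np.array(
        [
            [-(gl[0] + gax[0]), gax[0], 0.0],
            [gax[0], -(gl[1] + gax[0] + gax[1]), gax[1]],
            [0.0, gax[1], -(gl[2] + gax[1])],
        ]
    )
    A = lap / c[:, None]
    v0 = np.array([-50.0, -78.0, -90.0])

    dt = 0.0005
    n_sub = 10  # backward Euler converges O(dt); use small sub-steps
    v = v0.copy()
    m = np.zeros(3)
    h = np.zeros(3)
    n = np.zeros(3)
    spike_buf = np.zeros(64)
    run_fiber(
        v, m, h, n,
        c, gl, np.zeros(3), np.zeros(3), gax,
        66.0, -88.0, e_rest,
        dt, n_sub, 0,
        np.empty(0, dtype=np.int64),
        0.0, 0.1, 0.3, 0.0, 0,
        1, 1e9, 0.7,
        spike_buf,
        np.empty(0, dtype=np.int64), np.empty((0, 0)),
    )
    v_exact = e_rest + expm(A * dt * n_sub) @ (v0 - e_rest)
    assert np.abs(v - v_exact).max() < 1e-3 * np.abs(v_exact - e_rest).max()


def test_passive_steady_state_attenuation_matches_cable_theory():
    """Voltage decay along a uniform passive cable under steady current
    follows exp(-x/lambda), lambda = sqrt(R_m d / (4 R_a)), within 2%."""
    params = _passive_params()
    d_um, rm, ra = 1.2, 1662.0, 8291.4
    lam_um = np.sqrt(rm * d_um * 1e-4 / (4.0 * ra)) * 1e4
    length = 5.0 * lam_um
    n_comp = 400
    dx = length / n_comp
    area = np.pi * d_um * 1e-4 * dx * 1e-4
    c = np.full(n_comp, 0.05125 * area * 1e3)
    gl = np.full(n_comp, area / rm * 1e6)
    r_half = ra * (dx * 1e-4 / 2.0) / (np.pi * (d_um * 1e-4 / 2.0) ** 2)
    gax = np.full(n_comp - 1, 1e6 / (2.0 * r_half))

    g_src = 0.01  # uS source to 0 mV at compartment 0

    # oracle: direct linear steady-state solve of the discretized system
    lap = np.zeros((n_comp, n_comp))
    for i in range(n_comp):
        lap[i, i] -= gl[i]
        if i > 0:
            lap[i, i] -= gax[i - 1]
            lap[i, i - 1] += gax[i - 1]
        if i < n_comp - 1:
            lap[i, i] -= gax[i]
            lap[i, i + 1] += gax[i]
    lap[0, 0] -= g_src
    # steady state solves lap @ v + gl * e_rest = 0 (source reversal 0 mV)
    v_direct = np.linalg.solve(lap, -gl * (-78.0))
    depol = v_direct + 78.0

    # the interior decay follows exp(-x/lambda) within 2%
    x = (np.arange(n_comp) + 0.5) * dx
    sel = (x > 0.5 * lam_um) & (x < 3.0 * lam_um)
    ratio = depol[sel] / (
        depol[sel][0] * np.exp(-(x[sel] - x[sel][0]) / lam_um)
    )
    assert np.abs(ratio - 1.0).max() < 0.02

    # the implicit time stepper relaxes to the same steady state: use a
    # step-like synaptic conductance (tau1 tiny, tau2 huge)
    v = np.full(n_comp, -78.0)
    m = np.zeros(n_comp)
    h = np.zeros(n_comp)
    n = np.zeros(n_comp)
    spike_buf = np.zeros(64)
    run_fiber(
        v, m, h, n,
        c, gl, np.zeros(n_comp), np.zeros(n_comp), gax,
        66.0, -88.0, -78.0,
        0.005, 8000, 0,
        np.array([0], dtype=np.int64),
        g_src, 1e-3, 1e7, 0.0, 0,
        1, 1e9, 0.7,
        spike_buf,
        np.empty(0, dtype=np.int64), np.empty((0, 0)),
    )
    sel2 = x < 3.0 * lam_um
    np.testing.assert_allclose(v[sel2] + 78.0, depol[sel2], rtol=0.02)


def test_halving_dt_shifts_spike_time_by_less_than_10_us(control_grid):
    s1 = simulate_fiber(control_grid, [0.0], 5.0, dt=0.005)
    s2 = simulate_fiber(control_grid, [0.0], 5.0, dt=0.0025)
    assert s1.size == s2.size == 1
    assert abs(s1[0] - s2[0]) < 0.010


def test_spatial_refinement_keeps_spike_time(control_grid):
    fine = build_cable(FiberMorphology(), max_dx_unmyel=0.5, max_dx_myelin=5.0)
    s1 = simulate_fiber(control_grid, [0.0], 5.0)
    s2 = simulate_fiber(fine, [0.0], 5.0)
    assert s1.size == s2.size == 1
    assert abs(s1[0] - s2[0]) < 0.010


def test_action_potential_shape_and_initiation_site(control_grid):
    """The AP overshoots by > 60 mV from rest at excitable compartments
    and crosses threshold at the heminode before node 1."""
    g = control_grid
    idx = (g.idx_heminode, int(g.idx_nodes[0]))
    sp, t, v = simulate_fiber(g, [0.0], 5.0, record=idx)
    assert sp.size == 1
    assert v[0].max() - (-78.0) > 60.0
    assert v[1].max() - (-78.0) > 60.0
    # initiation site: the depolarization foot arrives at the heminode
    # before node 1 (the synaptic drive reaches it first)
    foot = -78.0 + 18.0
    t_hemi = t[np.argmax(v[0] >= foot)]
    t_node = t[np.argmax(v[1] >= foot)]
    assert t_hemi < t_node


def test_gating_variables_stay_in_unit_interval(control_grid):
    from hhlsim.cable.gating import steady_state as ss
    from hhlsim.cable.solver import MAX_SPIKES, run_fiber

    g = control_grid
    p = g.params
    m0, h0, n0 = ss(p.e_rest)
    nc = g.n_comp
    v = np.full(nc, p.e_rest)
    m = np.full(nc, m0)
    h = np.full(nc, h0)
    n = np.full(nc, n0)
    rel = np.array([0, 300, 600], dtype=np.int64)
    run_fiber(
        v, m, h, n,
        g.c_nF, g.g_leak_uS, g.g_na_uS, g.g_k_uS, g.g_axial_uS,
        p.e_na, p.e_k, p.e_rest,
        0.005, 1000, 0,
        rel,
        0.12e-3, 0.1, 0.3, 0.0, 0,
        g.idx_heminode, -20.0, 0.7,
        np.zeros(MAX_SPIKES),
        np.empty(0, dtype=np.int64), np.empty((0, 0)),
    )
    for arr in (m, h, n):
        assert np.all((arr >= 0.0) & (arr <= 1.0))
    assert np.all(np.isfinite(v))
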