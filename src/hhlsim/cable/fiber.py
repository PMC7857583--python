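"""Single-fiber simulation and analyses.

The synaptic event conductance follows a double-exponential time course
g(t) = c * A * (exp(-t/tau2) - exp(-t/tau1)) with reversal at 0 mV, the
standard waveform for an AMPA-type postsynaptic conductance.  ``A``
(default 0.12 nS) sets the event strength.  Two normalizations of the
prefactor are supported (see :class:`SynapticPulse`); the default makes
the peak conductance equal to A, which reproduces the documented
single-release behavior of a normal fiber (one release, one spike, and
spike failure for unmyelinated segments longer than ~11.6 um).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gating import steady_state
from .morphology import CableGrid, FiberMorphology, MembraneParams, build_cable
from .solver import MAX_SPIKES, run_fiber

DT_MS = 0.005           # 5 us implicit step
SETTLE_MS = 2.0
SPIKE_THRESH_MV = -20.0
SPIKE_DEAD_MS = 0.7

_DBLEXP_PEAK = {}


def _dblexp_peak(tau1: float, tau2: float) -> float:
    key = (tau1, tau2)
    if key not in _DBLEXP_PEAK:
        tpk = np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)
        _DBLEXP_PEAK[key] = np.exp(-tpk / tau2) - np.exp(-tpk / tau1)
    return _DBLEXP_PEAK[key]


@dataclass(frozen=True)
class SynapticPulse:
    """Conductance transient of one vesicle-release event.

    ``norm`` selects the prefactor convention:

    - ``"peak"`` (default): the conductance peaks at exactly ``A_nS``.
    - ``"printed"``: literal prefactor 0.39, i.e. the peak conductance is
      0.39 * 0.385 * A ~= 0.15 * A.  Kept for reference; at A = 0.12 nS
      this drive is far below single-event spike threshold.
    """

    A_nS: float = 0.12
    tau1_ms: float = 0.1
    tau2_ms: float = 0.3
    e_syn_mV: float = 0.0
    norm: str = "peak"

    def __post_init__(self):
        if not 0.0 < self.tau1_ms < self.tau2_ms:
            raise ValueError("need 0 < tau1 < tau2")
        if self.A_nS < 0:
            raise ValueError("A_nS must be >= 0")
        if self.norm not in ("peak", "printed"):
            raise ValueError("norm must be 'peak' or 'printed'")

    @property
    def g_peak_uS(self) -> float:
        """Peak conductance of one event, in uS."""
        if self.norm == "peak":
            return self.A_nS * 1e-3
        return 0.39 * _dblexp_peak(self.tau1_ms, self.tau2_ms) * self.A_nS * 1e-3

    def conductance(self, t_ms) -> np.ndarray:
        """g(t) in uS for time after onset (0 before onset)."""
        t = np.asarray(t_ms, dtype=float)
        wave = np.exp(-t / self.tau2_ms) - np.exp(-t / self.tau1_ms)
        return np.where(
            t >= 0.0,
            self.g_peak_uS * wave / _dblexp_peak(self.tau1_ms, self.tau2_ms),
            0.0,
        )


def simulate_fiber(
    grid: CableGrid,
    release_times_ms,
    duration_ms: float,
    pulse: SynapticPulse | None = None,
    dt: float = DT_MS,
    settle_ms: float = SETTLE_MS,
    record: tuple[int, ...] = (),
):
    """Simulate one fiber driven by a release train.

    Release times are in ms >= 0 (0 = end of settling); spike times at
    the heminode center are returned on the same clock.

    Returns ``spike_times`` or ``(spike_times, t, v_rec)`` when
    ``record`` lists compartment indices to trace.
    """
    if pulse is None:
        pulse = SynapticPulse()
    p = grid.params
    m0, h0, n0 = steady_state(p.e_rest)

    settle_steps = int(round(settle_ms / dt))
    n_steps = settle_steps + int(round(duration_ms / dt))

    rel = np.sort(np.asarray(release_times_ms, dtype=float))
    if rel.size and (rel[0] < 0 or rel[-1] > duration_ms):
        raise ValueError("release times must lie in [0, duration_ms]")
    rel_steps = settle_steps + np.rint(rel / dt).astype(np.int64)

    nc = grid.n_comp
    v = np.full(nc, p.e_rest)
    m = np.full(nc, m0)
    h = np.full(nc, h0)
    n = np.full(nc, n0)
    spike_buf = np.zeros(MAX_SPIKES)
    rec_idx = np.asarray(record, dtype=np.int64)
    rec_out = np.empty((rec_idx.size, n_steps + 1))

    n_spk = run_fiber(
        v, m, h, n,
        grid.c_nF, grid.g_leak_uS, grid.g_na_uS, grid.g_k_uS,
        grid.g_axial_uS,
        p.e_na, p.e_k, p.e_rest,
        dt, n_steps, settle_steps,
        rel_steps,
        pulse.g_peak_uS, pulse.tau1_ms, pulse.tau2_ms, pulse.e_syn_mV,
        grid.idx_synapse,
        grid.idx_heminode, SPIKE_THRESH_MV, SPIKE_DEAD_MS,
        spike_buf,
        rec_idx, rec_out,
    )
    spikes = spike_buf[:n_spk].copy()
    if rec_idx.size:
        t = np.arange(n_steps + 1) * dt - settle_ms
        return spikes, t, rec_out
    return spikes


def _peak_time(t: np.ndarray, v: np.ndarray) -> float:
    """Time of the maximum of v, refined by quadratic interpolation."""
    i = int(np.argmax(v))
    if 0 < i < v.size - 1:
        denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
        if denom != 0.0:
            return t[i] - 0.5 * (v[i + 1] - v[i - 1]) / denom * (t[1] - t[0])
    return t[i]


def _crossing_time(t: np.ndarray, v: np.ndarray, thresh: float) -> float:
    i = int(np.argmax(v >= thresh))
    if v[i] < thresh or i == 0:
        raise RuntimeError("trace never crosses the velocity threshold")
    frac = (thresh - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[1] - t[0]))


def conduction_velocity(
    grid: CableGrid,
    pulse: SynapticPulse | None = None,
    node_pair: tuple[int, int] = (0, 3),
    method: str = "foot",
    foot_depol_mV: float = 18.0,
    dt: float = DT_MS,
) -> float:
    """Propagation speed (m/s) between two node-of-Ranvier centers.

    A single suprathreshold synaptic event is delivered and the
    action-potential arrival times at the two nodes are compared.

    ``method="foot"`` (default) times the arrival of the AP foot — the
    first upward crossing of rest + ``foot_depol_mV`` — which measures
    the propagating depolarization front.  ``method="peak"`` uses the
    interpolated V_m peak times instead; on a fiber this short
    (~0.2 electrotonic length constants of the myelinated run) the
    spike peaks are nearly simultaneous everywhere, so the peak-based
    number is much larger and mostly reflects local loading rather than
    propagation.
    """
    i, j = node_pair
    idx = (int(grid.idx_nodes[i]), int(grid.idx_nodes[j]))
    spikes, t, v = simulate_fiber(
        grid, [0.0], duration_ms=5.0, pulse=pulse, dt=dt, record=idx
    )
    if spikes.size == 0 or max(v[0].max(), v[1].max()) < SPIKE_THRESH_MV:
        raise RuntimeError("no propagating spike; conduction velocity undefined")
    if method == "foot":
        thresh = grid.params.e_rest + foot_depol_mV
        t0 = _crossing_time(t, v[0], thresh)
        t1 = _crossing_time(t, v[1], thresh)
    elif method == "peak":
        t0 = _peak_time(t, v[0])
        t1 = _peak_time(t, v[1])
    else:
        raise ValueError("method must be 'foot' or 'peak'")
    if t1 <= t0:
        raise RuntimeError("spike arrival order inconsistent with propagation")
    dist_um = grid.x_center[idx[1]] - grid.x_center[idx[0]]
    return (dist_um * 1e-6) / ((t1 - t0) * 1e-3)


def single_release_delay(
    L_u: float,
    A_nS: float = 0.12,
    L_h: float = 1.0,
    convention: str = "default",
    params: MembraneParams | None = None,
    pulse: SynapticPulse | None = None,
    dt: float = DT_MS,
) -> float | None:
    """Heminode spike delay (ms) after one release, or None if no spike.

    A single synaptic event at t = 0 is applied to a fiber with the
    given unmyelinated-segment length; the delay is the heminode spike
    time.  Past a critical L_u a single event no longer triggers a
    spike and None is returned.
    """
    if pulse is None:
        pulse = SynapticPulse(A_nS=A_nS)
    else:
        pulse = replace(pulse, A_nS=A_nS)
    grid = build_cable(
        FiberMorphology(L_u=L_u, L_h=L_h), params=params, convention=convention
    )
    spikes = simulate_fiber(grid, [0.0], duration_ms=5.0, pulse=pulse, dt=dt)
    if spikes.size == 0:
        return None
    return float(spikes[0])


def critical_lu(
    A_nS: float = 0.12,
    lu_min: float = 10.0,
    lu_max: float = 13.0,
    step_um: float = 0.1,
    **kwargs,
) -> float:
    """Largest L_u (on a ``step_um`` grid) at which one release still spikes.

    Scans L_u upward; raises if even ``lu_min`` fails to spike.
    """
    n = int(round((lu_max - lu_min) / step_um))
    last_ok = None
    for k in range(n + 1):
        lu = lu_min + k * step_um
        if single_release_delay(lu, A_nS=A_nS, **kwargs) is not None:
            last_ok = lu
        elif last_ok is not None:
            break
    if last_ok is None:
        raise RuntimeError(f"no spike even at L_u = {lu_min} um (A = {A_nS} nS)")
    return round(last_ok, 10)
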