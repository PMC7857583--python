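"""End-to-end front end: sound stimulus -> per-synapse release rates.

A :class:`FrontendChain` fixes a stimulus and a parameter set and lazily
computes, per (best frequency, fiber type), the deterministic release
drive of the corresponding IHC synapse:

- ``k``: per-vesicle release hazard (1/s) on the simulation grid,
  driving the stochastic three-pool sampler, and
- ``rate``: the expected release rate q(t) k(t) (releases/s), driving
  the simplified inhomogeneous-Poisson sampler and exported as the
  synapse's :class:`ReleaseRateSeries`.

The deterministic chain is identical across trials; only release
sampling is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..stimulus import SoundStimulus
from .filters import drnl_channel, middle_ear_filter
from .ihc import ihc_transduction, release_rate, resting_state
from .params import FIBER_TYPES, FrontendParams, load_frontend_params
from .synapse import expected_release_rate, sample_release_train

S1_LEVEL_CUTOFF_DB = {"HT": 30.0, "MT": 15.0, "LT": None}


@dataclass
class ReleaseRateSeries:
    """Expected instantaneous release rate of one synapse."""

    synapse_id: int
    times_ms: np.ndarray
    rate_per_s: np.ndarray          # expected release rate q(t) k(t)
    k_per_s: np.ndarray | None = None  # per-vesicle hazard (pools model)

    def __post_init__(self):
        if np.any(self.rate_per_s < 0):
            raise ValueError("release rate must be nonnegative")


def apply_s1_threshold_modification(
    rate: np.ndarray, fiber_type: str, level_db: float
) -> np.ndarray:
    """Zero the drive of HT (<30 dB) and MT (<15 dB) synapses.

    This sharpens the separation of the class response thresholds; LT
    fibers are never modified.
    """
    cutoff = S1_LEVEL_CUTOFF_DB.get(fiber_type)
    if cutoff is not None and level_db < cutoff:
        return np.zeros_like(rate)
    return rate


class FrontendChain:
    """Deterministic cochlear processing of one stimulus."""

    def __init__(
        self,
        stimulus: SoundStimulus,
        params: FrontendParams | None = None,
    ):
        self.stimulus = stimulus
        self.params = params if params is not None else load_frontend_params()
        self.fs_hz = 1e3 / stimulus.sample_interval
        self._stapes = None
        self._cache: dict[tuple[float, str], dict] = {}

    @property
    def stapes_velocity(self) -> np.ndarray:
        if self._stapes is None:
            me = self.params.middle_ear
            self._stapes = middle_ear_filter(
                self.stimulus.pressure_pa,
                self.fs_hz,
                f_lo_hz=me.f_lo_hz,
                f_hi_hz=me.f_hi_hz,
                order=me.order,
                gain=me.stapes_gain,
            )
        return self._stapes

    def bm_velocity(self, bf_hz: float, fiber_type: str) -> np.ndarray:
        d = self.params.drnl
        tp = self.params.type_params(fiber_type)
        return drnl_channel(
            self.stapes_velocity,
            self.fs_hz,
            bf_hz,
            n_lin=tp.n_lin,
            lin_gain=d.lin_gain,
            lin_bw_factor=d.lin_bw_factor,
            nl_order=d.nl_order,
            nl_a=d.nl_a,
            nl_b=d.nl_b,
            nl_c=d.nl_c,
            bw_hz=d.bw_hz(bf_hz),
        )

    def drive(self, bf_hz: float, fiber_type: str) -> dict:
        """Per-vesicle hazard and expected release rate for one synapse."""
        key = (float(bf_hz), fiber_type)
        if key not in self._cache:
            p = self.params
            tp = p.type_params(fiber_type)
            ca = ihc_transduction(
                self.bm_velocity(bf_hz, fiber_type),
                self.stimulus.sample_interval,
                p.ihc,
                tp.g_ca_max_nS,
            )
            k = release_rate(ca, tp.ca_thr, p.z)
            if p.s1_threshold_mod:
                k = apply_s1_threshold_modification(
                    k, fiber_type, self.stimulus.level
                )
            rate = expected_release_rate(
                k, self.stimulus.sample_interval, p.pools
            )
            self._cache[key] = {"k": k, "rate": rate}
        return self._cache[key]

    def release_series(
        self, bf_hz: float, fiber_type: str, synapse_id: int = 0
    ) -> ReleaseRateSeries:
        d = self.drive(bf_hz, fiber_type)
        return ReleaseRateSeries(
            synapse_id=synapse_id,
            times_ms=self.stimulus.times,
            rate_per_s=d["rate"],
            k_per_s=d["k"],
        )

    def sample_train(
        self,
        bf_hz: float,
        fiber_type: str,
        master_seed: int,
        trial: int,
        synapse_id: int,
    ) -> np.ndarray:
        """One stochastic release train (ms) for one synapse."""
        d = self.drive(bf_hz, fiber_type)
        p = self.params
        if p.release_model == "pools":
            series = d["k"]
        else:
            series = d["rate"]
        return sample_release_train(
            series,
            self.stimulus.sample_interval,
            pools=p.pools,
            model=p.release_model,
            master_seed=master_seed,
            trial=trial,
            synapse_id=synapse_id,
        )


def spontaneous_release_rate(
    params: FrontendParams, fiber_type: str
) -> float:
    """Resting expected release rate (releases/s) of one synapse class."""
    tp = params.type_params(fiber_type)
    _, _, ca0 = resting_state(params.ihc, tp.g_ca_max_nS)
    k0 = float(release_rate(np.array([ca0]), tp.ca_thr, params.z)[0])
    q0, _, _ = params.pools.steady_state(k0)
    return q0 * k0


def rate_intensity_curve(
    levels_db,
    fiber_type: str,
    params: FrontendParams | None = None,
    frequency_hz: float = 10e3,
    bf_hz: float = 10e3,
    duration_ms: float = 50.0,
    n_fibers: int = 20,
    master_seed: int = 1234,
    lu_um: float = 10.0,
) -> np.ndarray:
    """Mean SGN discharge rate (spikes/s) vs level for one fiber class.

    Runs the full chain — release sampling plus cable simulation — on a
    long tone and counts heminode spikes over the stimulus window.
    Used to verify the class calibration (spontaneous rate ranges,
    LT saturation by ~30 dB, HT threshold above ~20 dB).
    """
    from ..cable import FiberMorphology, build_cable, simulate_fiber

    if params is None:
        params = load_frontend_params()
    grid = build_cable(FiberMorphology(L_u=lu_um))
    rates = []
    for level in np.atleast_1d(levels_db):
        stim = SoundStimulus(
            frequency=frequency_hz, level=level, duration=duration_ms,
            onset_time=1.0, total_sim_time=duration_ms + 2.0,
        )
        chain = FrontendChain(stim, params)
        n_spk = 0
        for i in range(n_fibers):
            rel = chain.sample_train(bf_hz, fiber_type, master_seed, i, 0)
            spikes = simulate_fiber(grid, rel, stim.total_sim_time)
            sel = (spikes >= stim.onset_time) & (
                spikes <= stim.onset_time + duration_ms
            )
            n_spk += int(sel.sum())
        rates.append(n_spk / n_fibers / (duration_ms * 1e-3))
    return np.asarray(rates)
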