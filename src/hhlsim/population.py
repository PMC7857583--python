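"""Fiber populations, lesion scenarios and trial execution.

A population is a list of :class:`FiberSpec`.  The default (control)
population carries 21 best frequencies on the Greenwood map between
5.6 and 32 kHz with 100 low-, 100 medium- and 100 high-threshold
fibers per BF (6300 fibers), all with the control geometry L_u = 10 um,
L_h = 1 um.  ``n_per_type`` scales the per-BF counts down for
desk-scale runs; CAP waveforms are rescaled to full-population
equivalents downstream (the CAP is a sum over fibers, so a uniform
subsample is an unbiased estimate of the full sum).

Lesions are applied in a fixed order (myelinopathy first, then
synaptopathy); both only mutate specs, never remove them.  Synaptopathy
is a binary mask: a fiber without a synapse receives no releases and
therefore never spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cable import FiberMorphology, MembraneParams, SynapticPulse, build_cable
from .cable.gating import steady_state
from .cable.solver import MAX_SPIKES, build_gating_tables, run_population
from .frontend import FrontendChain, FrontendParams, greenwood_channels, load_frontend_params
from .frontend.params import FIBER_TYPES
from .stimulus import SoundStimulus

CONTROL_LU_UM = 10.0
CONTROL_LH_UM = 1.0

MYELINOPATHY_MODES = (
    "homogeneous_Lu",
    "homogeneous_Lh",
    "heterogeneous_Lu",
    "heterogeneous_Lh",
    "heterogeneous_both",
)
SYNAPTOPATHY_MODES = ("HT", "random_third")


@dataclass
class FiberSpec:
    fiber_id: int
    bf_hz: float
    fiber_type: str
    L_u: float = CONTROL_LU_UM
    L_h: float = CONTROL_LH_UM
    convention: str = "default"
    synapse_present: bool = True

    def __post_init__(self):
        if self.fiber_type not in FIBER_TYPES:
            raise ValueError(f"unknown fiber type {self.fiber_type!r}")


def build_population(
    n_bfs: int = 21,
    n_per_type: int = 100,
    f_min_hz: float = 5.6e3,
    f_max_hz: float = 32e3,
    convention: str = "default",
) -> list[FiberSpec]:
    """Control population: n_bfs x (3 * n_per_type) fibers."""
    if n_bfs * n_per_type == 0:
        warnings.warn("building an empty population", stacklevel=2)
        return []
    bfs = greenwood_channels(n_bfs, f_min_hz, f_max_hz)
    specs = []
    fid = 0
    for bf in bfs:
        for ftype in FIBER_TYPES:
            for _ in range(n_per_type):
                specs.append(
                    FiberSpec(fiber_id=fid, bf_hz=float(bf), fiber_type=ftype,
                              convention=convention)
                )
                fid += 1
    return specs


def apply_myelinopathy(
    specs: list[FiberSpec],
    mode: str,
    rng: np.random.Generator,
    L_u: float | None = None,
    L_h: float | None = None,
    fraction_increase: float = 1.0,
    L_h_max: float = 6.0,
) -> list[FiberSpec]:
    """Return new specs with disrupted myelin geometry.

    Homogeneous modes set every fiber to the given length; heterogeneous
    modes draw per fiber L_u ~ U[10, 10 (1 + f)] um and/or
    L_h ~ U[1, L_h_max] um with the scenario RNG.
    """
    if mode not in MYELINOPATHY_MODES:
        raise ValueError(f"unknown myelinopathy mode {mode!r}")
    out = []
    for s in specs:
        lu, lh = s.L_u, s.L_h
        if mode == "homogeneous_Lu":
            if L_u is None or L_u < CONTROL_LU_UM:
                raise ValueError("homogeneous L_u below the control 10 um")
            lu = L_u
        elif mode == "homogeneous_Lh":
            if L_h is None or L_h < CONTROL_LH_UM:
                raise ValueError("homogeneous L_h below the control 1 um")
            lh = L_h
        else:
            if mode in ("heterogeneous_Lu", "heterogeneous_both"):
                lu = rng.uniform(
                    CONTROL_LU_UM, CONTROL_LU_UM * (1.0 + fraction_increase)
                )
            if mode in ("heterogeneous_Lh", "heterogeneous_both"):
                lh = rng.uniform(CONTROL_LH_UM, L_h_max)
        out.append(replace(s, L_u=lu, L_h=lh))
    return out


def apply_synaptopathy(
    specs: list[FiberSpec], mode: str, rng: np.random.Generator
) -> list[FiberSpec]:
    """Mask synapses: all HT fibers, or a uniformly random third."""
    if mode not in SYNAPTOPATHY_MODES:
        raise ValueError(f"unknown synaptopathy mode {mode!r}")
    out = [replace(s) for s in specs]
    if mode == "HT":
        for s in out:
            if s.fiber_type == "HT":
                s.synapse_present = False
    else:
        n_remove = len(out) // 3
        idx = rng.choice(len(out), size=n_remove, replace=False)
        for i in idx:
            out[i].synapse_present = False
    return out


@dataclass
class PopulationScenario:
    """Everything needed to run one in-silico experiment."""

    specs: list[FiberSpec]
    stimulus: SoundStimulus
    label: str = "custom"
    master_seed: int = 0
    n_trials: int = 50
    frontend: FrontendParams | None = None
    membrane: MembraneParams = field(default_factory=MembraneParams)
    pulse: SynapticPulse = field(default_factory=SynapticPulse)

    @property
    def scale_to_full(self) -> float:
        """Factor mapping this population's CAP to the 6300-fiber scale."""
        return 6300.0 / len(self.specs) if self.specs else 1.0


SCENARIO_REGISTRY = {
    "control": {},
    "hom_lu_11": {"myelinopathy": {"mode": "homogeneous_Lu", "L_u": 11.0}},
    "hom_lu_15": {"myelinopathy": {"mode": "homogeneous_Lu", "L_u": 15.0}},
    "hom_lu_20": {"myelinopathy": {"mode": "homogeneous_Lu", "L_u": 20.0}},
    "hom_lh_2": {"myelinopathy": {"mode": "homogeneous_Lh", "L_h": 2.0}},
    "hom_lh_6": {"myelinopathy": {"mode": "homogeneous_Lh", "L_h": 6.0}},
    "het_lu": {"myelinopathy": {"mode": "heterogeneous_Lu",
                                "fraction_increase": 1.0}},
    "het_lh": {"myelinopathy": {"mode": "heterogeneous_Lh", "L_h_max": 6.0}},
    "synaptopathy_ht": {"synaptopathy": {"mode": "HT"}},
    "synaptopathy_random": {"synaptopathy": {"mode": "random_third"}},
    # combined hidden-hearing-loss cases
    "case1": {"synaptopathy": {"mode": "HT"}},
    "case2": {"myelinopathy": {"mode": "heterogeneous_Lu",
                               "fraction_increase": 1.0}},
    "case3": {"myelinopathy": {"mode": "heterogeneous_Lu",
                               "fraction_increase": 1.0},
              "synaptopathy": {"mode": "HT"}},
    "case4": {"myelinopathy": {"mode": "heterogeneous_both",
                               "fraction_increase": 1.0, "L_h_max": 6.0}},
}


def make_scenario(
    label: str,
    stimulus: SoundStimulus,
    n_bfs: int = 21,
    n_per_type: int = 100,
    master_seed: int = 0,
    n_trials: int = 50,
    frontend: FrontendParams | None = None,
    convention: str = "default",
) -> PopulationScenario:
    """Instantiate a registered scenario.

    Lesion draws use a dedicated RNG stream derived from the master
    seed, so the same seed yields the same lesioned population
    regardless of trial count.  Myelinopathy is applied before
    synaptopathy.
    """
    if label not in SCENARIO_REGISTRY:
        raise KeyError(
            f"unknown scenario {label!r}; registered: "
            f"{sorted(SCENARIO_REGISTRY)}"
        )
    cfg = SCENARIO_REGISTRY[label]
    specs = build_population(
        n_bfs=n_bfs, n_per_type=n_per_type, convention=convention
    )
    rng = np.random.default_rng([master_seed, 946424126])  # lesion stream
    if "myelinopathy" in cfg:
        specs = apply_myelinopathy(specs, rng=rng, **cfg["myelinopathy"])
    if "synaptopathy" in cfg:
        specs = apply_synaptopathy(specs, rng=rng, **cfg["synaptopathy"])
    return PopulationScenario(
        specs=specs, stimulus=stimulus, label=label,
        master_seed=master_seed, n_trials=n_trials, frontend=frontend,
    )


@dataclass
class TrialResult:
    scenario_label: str
    trial: int
    release_trains: list
    spike_trains: list


class PopulationRunner:
    """Runs trials of one scenario, reusing grids and front-end drive."""

    def __init__(self, scenario: PopulationScenario):
        self.scenario = scenario
        self.chain = FrontendChain(
            scenario.stimulus,
            scenario.frontend
            if scenario.frontend is not None
            else load_frontend_params(),
        )
        self._pack = None

    def _packed_grids(self):
        """Concatenate per-fiber grid arrays for the batch kernel."""
        if self._pack is not None:
            return self._pack
        sc = self.scenario
        grid_cache = {}
        grids = []
        for s in sc.specs:
            key = (round(s.L_u, 6), round(s.L_h, 6), s.convention)
            if key not in grid_cache:
                grid_cache[key] = build_cable(
                    FiberMorphology(L_u=s.L_u, L_h=s.L_h),
                    params=sc.membrane,
                    convention=s.convention,
                )
            grids.append(grid_cache[key])
        comp_off = np.zeros(len(grids) + 1, dtype=np.int64)
        ax_off = np.zeros(len(grids) + 1, dtype=np.int64)
        for i, g in enumerate(grids):
            comp_off[i + 1] = comp_off[i] + g.n_comp
            ax_off[i + 1] = ax_off[i] + g.n_comp - 1
        c_nF = np.concatenate([g.c_nF for g in grids])
        g_leak = np.concatenate([g.g_leak_uS for g in grids])
        g_na = np.concatenate([g.g_na_uS for g in grids])
        g_k = np.concatenate([g.g_k_uS for g in grids])
        g_ax = np.concatenate([g.g_axial_uS for g in grids])
        detect = np.array([g.idx_heminode for g in grids], dtype=np.int64)
        self._pack = (comp_off, c_nF, g_leak, g_na, g_k, g_ax, ax_off, detect)
        return self._pack

    def run_trial(self, trial: int) -> TrialResult:
        """One stochastic trial: sample releases, run all cables."""
        from .cable.fiber import (
            DT_MS,
            SETTLE_MS,
            SPIKE_DEAD_MS,
            SPIKE_THRESH_MV,
        )

        sc = self.scenario
        stim = sc.stimulus
        release_trains = []
        for s in sc.specs:
            if s.synapse_present:
                rel = self.chain.sample_train(
                    s.bf_hz, s.fiber_type, sc.master_seed, trial, s.fiber_id
                )
            else:
                rel = np.empty(0)
            release_trains.append(rel)

        comp_off, c_nF, g_leak, g_na, g_k, g_ax, ax_off, detect = (
            self._packed_grids()
        )
        rel_off = np.zeros(len(release_trains) + 1, dtype=np.int64)
        for i, r in enumerate(release_trains):
            rel_off[i + 1] = rel_off[i] + r.size
        rel_flat = (
            np.concatenate(release_trains)
            if rel_off[-1] > 0
            else np.empty(0)
        )

        p = sc.membrane
        m0, h0, n0 = steady_state(p.e_rest)
        settle_steps = int(round(SETTLE_MS / DT_MS))
        n_steps = settle_steps + int(round(stim.total_sim_time / DT_MS))
        spikes_out = np.zeros((len(sc.specs), MAX_SPIKES))
        n_spk_out = np.zeros(len(sc.specs), dtype=np.int64)
        run_population(
            comp_off, c_nF, g_leak, g_na, g_k, g_ax, ax_off, detect,
            p.e_na, p.e_k, p.e_rest,
            m0, h0, n0,
            DT_MS, n_steps, settle_steps,
            rel_flat, rel_off,
            sc.pulse.g_peak_uS, sc.pulse.tau1_ms, sc.pulse.tau2_ms,
            sc.pulse.e_syn_mV,
            SPIKE_THRESH_MV, SPIKE_DEAD_MS,
            spikes_out, n_spk_out,
            build_gating_tables(DT_MS),
        )
        spike_trains = [
            spikes_out[i, : n_spk_out[i]].copy()
            for i in range(len(sc.specs))
        ]
        return TrialResult(
            scenario_label=sc.label,
            trial=trial,
            release_trains=release_trains,
            spike_trains=spike_trains,
        )

    def run_trials(self, n_trials: int | None = None) -> list[TrialResult]:
        n = n_trials if n_trials is not None else self.scenario.n_trials
        return [self.run_trial(t) for t in range(n)]


def synchrony_experiment(
    heterogeneity_fractions=(0.0, 0.25, 0.5, 1.0),
    level_db: float = 80.0,
    n_fibers: int = 100,
    master_seed: int = 0,
    frontend: FrontendParams | None = None,
    bf_hz: float = 10e3,
    bin_width_ms: float = 0.05,
):
    """Shared-input synchrony experiment across L_u heterogeneity levels.

    A population of LT fibers at ~10 kHz BF all receive the *same*
    release train (one draw per heterogeneity level); returns, per
    fraction f, the spike trains, mean firing rate over the stimulus
    window and the pairwise-interval SD.  Spike synchrony degrades and
    the population rate falls as heminode positions spread out.
    """
    from .capx import pairwise_interval_histogram

    stim = SoundStimulus(frequency=bf_hz, level=level_db, duration=5.0,
                         onset_time=1.0, total_sim_time=10.0)
    chain = FrontendChain(
        stim, frontend if frontend is not None else load_frontend_params()
    )
    shared_rel = chain.sample_train(bf_hz, "LT", master_seed, 0, 0)
    results = {}
    for f in heterogeneity_fractions:
        rng = np.random.default_rng([master_seed, int(f * 1000), 7])
        lus = (
            np.full(n_fibers, CONTROL_LU_UM)
            if f == 0.0
            else rng.uniform(
                CONTROL_LU_UM, CONTROL_LU_UM * (1 + f), size=n_fibers
            )
        )
        trains = []
        from .cable import simulate_fiber

        for lu in lus:
            grid = build_cable(FiberMorphology(L_u=float(lu)))
            trains.append(
                simulate_fiber(grid, shared_rel, stim.total_sim_time)
            )
        rate = (
            sum(t.size for t in trains)
            / n_fibers
            / (stim.total_sim_time * 1e-3)
        )
        hist = pairwise_interval_histogram(trains, bin_width=bin_width_ms)
        results[f] = {
            "spike_trains": trains,
            "firing_rate_per_s": rate,
            "interval_sd_ms": hist.sd,
            "histogram": hist,
        }
    return results
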