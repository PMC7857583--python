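"""Scenario sweeps, combined hidden-hearing-loss cases and reporting.

Results are long-format :class:`pandas.DataFrame` tables with one row
per (scenario, level, trial, metric).  Per-trial CAP metrics support
the Welch comparisons; the headline numbers (amplitude, latency,
width) are measured on the trial-averaged CAP, which is how CAPs are
read experimentally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .capx import (
    average_caps,
    compute_cap,
    compare_scenarios,
    measure_cap,
    spike_latency_stats,
    spike_probability,
)
from .frontend import FrontendParams, load_frontend_params
from .io import ensure_dir, write_release_rate_series, write_spike_trains
from .population import PopulationRunner, make_scenario
from .stimulus import SoundStimulus

DEFAULT_LEVELS_DB = tuple(range(0, 81, 10))
CAP_GRID_DT_MS = 0.005


@dataclass
class SweepSpec:
    """A scenario x level x trial factorial experiment."""

    scenario_labels: tuple = ("control",)
    levels_db: tuple = DEFAULT_LEVELS_DB
    n_trials: int = 50
    master_seed: int = 0
    n_bfs: int = 21
    n_per_type: int = 100
    frequency_hz: float = 10e3
    duration_ms: float = 5.0
    onset_ms: float = 2.0
    tail_ms: float = 5.0
    frontend: FrontendParams | None = None

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for lev in self.levels_db:
            if not 0 <= lev <= 80:
                raise ValueError("levels outside the validated 0-80 dB range")

    def stimulus(self, level_db: float) -> SoundStimulus:
        return SoundStimulus(
            frequency=self.frequency_hz,
            level=level_db,
            duration=self.duration_ms,
            onset_time=self.onset_ms,
            total_sim_time=self.onset_ms + self.duration_ms + self.tail_ms,
        )


def run_scenario_level(
    spec: SweepSpec, label: str, level_db: float
) -> tuple[dict, pd.DataFrame]:
    """Run one scenario at one level; return summary dict + trial rows."""
    stim = spec.stimulus(level_db)
    scenario = make_scenario(
        label,
        stim,
        n_bfs=spec.n_bfs,
        n_per_type=spec.n_per_type,
        master_seed=spec.master_seed,
        n_trials=spec.n_trials,
        frontend=spec.frontend,
    )
    runner = PopulationRunner(scenario)
    caps, rows = [], []
    sp_list, lat_list = [], []
    for trial in range(spec.n_trials):
        res = runner.run_trial(trial)
        cap = compute_cap(
            res.spike_trains,
            dt=CAP_GRID_DT_MS,
            t_max=stim.total_sim_time,
            scale=scenario.scale_to_full,
        )
        caps.append(cap)
        trial_metrics = {}
        try:
            m = measure_cap(cap, t_start=stim.onset_time)
            trial_metrics.update(
                amplitude_uV=m.amplitude_uV,
                latency_ms=m.latency_ms,
                width_ms=m.width_ms,
            )
        except ValueError:
            pass
        try:
            sp = spike_probability(res.release_trains, res.spike_trains)
            trial_metrics["spike_probability"] = sp
            sp_list.append(sp)
        except ValueError:
            pass
        try:
            lat_m, lat_sd = spike_latency_stats(
                res.release_trains, res.spike_trains
            )
            trial_metrics["release_spike_latency_ms"] = lat_m
            trial_metrics["release_spike_latency_sd_ms"] = lat_sd
            lat_list.append(lat_m)
        except ValueError:
            pass
        for metric, value in trial_metrics.items():
            rows.append(
                {
                    "scenario": label,
                    "level_db": level_db,
                    "trial": trial,
                    "metric": metric,
                    "value": value,
                }
            )
    avg = average_caps(caps)
    summary = {
        "scenario": label,
        "level_db": level_db,
        "n_trials": spec.n_trials,
        "spike_probability": float(np.mean(sp_list)) if sp_list else np.nan,
        "release_spike_latency_ms": (
            float(np.mean(lat_list)) if lat_list else np.nan
        ),
    }
    try:
        m = measure_cap(avg, t_start=stim.onset_time)
        summary.update(
            amplitude_uV=m.amplitude_uV,
            latency_ms=m.latency_ms,
            width_ms=m.width_ms,
        )
    except ValueError:
        summary.update(
            amplitude_uV=np.nan, latency_ms=np.nan, width_ms=np.nan
        )
    return summary, pd.DataFrame(rows)


def run_level_sweep(spec: SweepSpec):
    """Full factorial sweep.

    Returns ``(summary_df, trials_df)``: per-(scenario, level) averaged
    CAP metrics and the long-format per-trial table.
    """
    summaries, trial_frames = [], []
    for label in spec.scenario_labels:
        for level in spec.levels_db:
            summary, trials = run_scenario_level(spec, label, level)
            summaries.append(summary)
            trial_frames.append(trials)
    return pd.DataFrame(summaries), pd.concat(trial_frames, ignore_index=True)


COMBINED_CASES = ("control", "case1", "case2", "case3", "case4")


def run_combined_cases(
    master_seed: int = 0,
    levels_db=(70.0,),
    n_trials: int = 50,
    n_per_type: int = 100,
    n_bfs: int = 21,
    frontend: FrontendParams | None = None,
):
    """The combined synaptopathy/myelinopathy case battery.

    Case 1 = HT synaptopathy; Case 2 = heterogeneous L_u (uniform
    [10, 20] um); Case 3 = Case 1 + Case 2; Case 4 = heterogeneous L_u
    and heterogeneous L_h (uniform [1, 6] um).
    """
    spec = SweepSpec(
        scenario_labels=COMBINED_CASES,
        levels_db=tuple(levels_db),
        n_trials=n_trials,
        master_seed=master_seed,
        n_per_type=n_per_type,
        n_bfs=n_bfs,
        frontend=frontend,
    )
    return run_level_sweep(spec)


def percent_of_control_table(
    trials_df: pd.DataFrame,
    control_label: str = "control",
    metrics=("amplitude_uV", "latency_ms", "width_ms"),
) -> pd.DataFrame:
    """Relative-change report with SEM and Welch significance marks.

    For every (scenario, level, metric), per-trial values are compared
    against the control scenario at the same level.  Control rows show
    0% change by construction.  The Welch test is a stand-in for the
    unnamed significance test behind published group comparisons.
    """
    rows = []
    for (label, level, metric), grp in trials_df.groupby(
        ["scenario", "level_db", "metric"]
    ):
        if metric not in metrics:
            continue
        ctrl = trials_df[
            (trials_df.scenario == control_label)
            & (trials_df.level_db == level)
            & (trials_df.metric == metric)
        ]["value"].to_numpy()
        vals = grp["value"].to_numpy()
        if ctrl.size < 2 or vals.size < 2:
            continue
        cmp = compare_scenarios(vals, ctrl)
        stars = (
            "#" if cmp.p_value < 0.001
            else "**" if cmp.p_value < 0.01
            else "*" if cmp.p_value < 0.05
            else ""
        )
        rows.append(
            {
                "scenario": label,
                "level_db": level,
                "metric": metric,
                "mean": cmp.mean_a,
                "control_mean": cmp.mean_b,
                "difference": cmp.difference,
                "percent_of_control": (
                    0.0 if label == control_label else cmp.percent_of_control
                ),
                "sem": cmp.se_difference,
                "n_trials": cmp.n_a,
                "p_value": cmp.p_value,
                "significance": "" if label == control_label else stars,
            }
        )
    return pd.DataFrame(rows)


def report(results_dir) -> pd.DataFrame:
    """Rebuild the percent-of-control report from archived results."""
    results_dir = Path(results_dir)
    trials_path = results_dir / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"no trials.csv under {results_dir}")
    trials = pd.read_csv(trials_path)
    table = percent_of_control_table(trials)
    table.to_csv(results_dir / "percent_of_control.csv", index=False)
    return table


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write small canned inputs for regression tests and demos.

    Release-rate series for 3 fiber types x 3 levels, a 30-fiber
    mini-population config, and its reference spike trains (trial 0).
    """
    out = ensure_dir(out_dir)
    params = load_frontend_params()
    manifest = {"seed": seed, "files": []}

    from .frontend import FrontendChain

    levels = (20.0, 50.0, 80.0)
    for level in levels:
        stim = SoundStimulus(
            frequency=10e3, level=level, duration=5.0,
            onset_time=2.0, total_sim_time=12.0,
        )
        chain = FrontendChain(stim, params)
        series = [
            chain.release_series(10e3, ftype, synapse_id=i)
            for i, ftype in enumerate(("LT", "MT", "HT"))
        ]
        path = out / f"release_rates_{int(level)}db.csv"
        write_release_rate_series(path, series)
        manifest["files"].append(path.name)

    spec = SweepSpec(
        scenario_labels=("control",),
        levels_db=(70.0,),
        n_trials=1,
        master_seed=seed,
        n_bfs=2,
        n_per_type=5,
    )
    scenario = make_scenario(
        "control", spec.stimulus(70.0), n_bfs=2, n_per_type=5,
        master_seed=seed,
    )
    res = PopulationRunner(scenario).run_trial(0)
    path = out / "mini_population_spikes.csv"
    write_spike_trains(path, res.spike_trains)
    manifest["files"].append(path.name)

    config = {
        "population": {"n_bfs": 2, "n_per_type": 5,
                       "f_min_hz": 5600.0, "f_max_hz": 32000.0},
        "stimulus": {"frequency_hz": 10000.0, "level_db": 70.0,
                     "duration_ms": 5.0},
        "seed": seed,
        "n_trials": 1,
    }
    with open(out / "mini_population.json", "w") as fh:
        json.dump(config, fh, indent=2)
    manifest["files"].append("mini_population.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_run_manifest(out_dir, spec: SweepSpec, extra: dict | None = None):
    """Provenance record: every resolved parameter value plus the seed."""
    import hhlsim

    from .frontend.params import dump_frontend_params

    out = ensure_dir(out_dir)
    fe = spec.frontend if spec.frontend is not None else load_frontend_params()
    dump_frontend_params(fe, out / "frontend_params_resolved.yaml")
    manifest = {
        "version": hhlsim.__version__,
        "master_seed": spec.master_seed,
        "scenarios": list(spec.scenario_labels),
        "levels_db": list(spec.levels_db),
        "n_trials": spec.n_trials,
        "n_bfs": spec.n_bfs,
        "n_per_type": spec.n_per_type,
    }
    if extra:
        manifest.update(extra)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
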