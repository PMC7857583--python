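"""Plain-text (CSV/YAML/JSON) readers and writers for the artifact's
external interfaces: release-rate series, release/spike trains, CAP
waveforms, metrics tables and interval histograms."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .capx import CAPWaveform, IntervalHistogram


def write_release_rate_series(path, series_list) -> None:
    """CSV columns: synapse_id, time_ms, rate_per_s."""
    frames = [
        pd.DataFrame(
            {
                "synapse_id": s.synapse_id,
                "time_ms": s.times_ms,
                "rate_per_s": s.rate_per_s,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_release_rate_series(path):
    """Load release-rate series; returns list of ReleaseRateSeries."""
    from .frontend.chain import ReleaseRateSeries

    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for sid, grp in df.groupby("synapse_id", sort=True):
        out.append(
            ReleaseRateSeries(
                synapse_id=int(sid),
                times_ms=grp["time_ms"].to_numpy(),
                rate_per_s=grp["rate_per_s"].to_numpy(),
            )
        )
    return out


def write_trains(path, trains, id_col: str, time_col: str) -> None:
    rows_id, rows_t = [], []
    for i, tr in enumerate(trains):
        rows_id.extend([i] * len(tr))
        rows_t.extend(np.asarray(tr, dtype=float))
    pd.DataFrame({id_col: rows_id, time_col: rows_t}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trains(path, id_col: str, time_col: str, n: int | None = None):
    df = pd.read_csv(path, float_precision="round_trip")
    n_trains = (int(df[id_col].max()) + 1) if len(df) else 0
    if n is not None:
        n_trains = max(n_trains, n)
    trains = [np.empty(0) for _ in range(n_trains)]
    for fid, grp in df.groupby(id_col):
        trains[int(fid)] = np.sort(grp[time_col].to_numpy())
    return trains


def write_spike_trains(path, trains) -> None:
    write_trains(path, trains, "fiber_id", "spike_time_ms")


def read_spike_trains(path, n: int | None = None):
    return read_trains(path, "fiber_id", "spike_time_ms", n=n)


def write_release_trains(path, trains) -> None:
    write_trains(path, trains, "synapse_id", "release_time_ms")


def read_release_trains(path, n: int | None = None):
    return read_trains(path, "synapse_id", "release_time_ms", n=n)


def write_cap_waveform(path, cap: CAPWaveform) -> None:
    pd.DataFrame(
        {"time_ms": cap.times, "voltage_uV": cap.voltage}
    ).to_csv(path, index=False, float_format="%.17g")


def read_cap_waveform(path) -> CAPWaveform:
    df = pd.read_csv(path, float_precision="round_trip")
    return CAPWaveform(
        times=df["time_ms"].to_numpy(), voltage=df["voltage_uV"].to_numpy()
    )


def write_interval_histogram(path, hist: IntervalHistogram,
                             norm_constant: float | None = None) -> None:
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    pd.DataFrame(
        {
            "bin_center_ms": centers,
            "count": hist.counts,
            "normalized_count": hist.normalized(norm_constant),
        }
    ).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
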