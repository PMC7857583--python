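"""Compound action potential synthesis and spike-train statistics.

The population CAP is synthesized by convolving every heminode spike
with a stereotyped extracellular unitary response U(t) and summing:
CAP(t) = sum_s U(t - s).  U(t) is a damped sinusoid

    U(t) = A exp(-k (t - t0)) sin(2 pi f (t - t0)),   t0 = 0.288 ms

supported on [-0.215, 2.785] ms and zero outside, with A = 0.16 uV,
k = 1.44 /ms and f = 0.994 kHz (the frequency inside the sine is read
as kHz so the oscillation period is ~1 ms).  The support starts half a
period before t0, so the leading deflection of each spike's
contribution — and hence the first CAP peak — is negative.

Peak metrics of the averaged CAP follow the usual ABR wave-1 reading:
amplitude a = |p - b| from baseline b to first peak p, latency
l = t_p - t_start from stimulus onset, and width w = twice the distance
from the preceding half-amplitude crossing to the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

U_AMP_UV = 0.16
U_K_PER_MS = 1.44
U_F_KHZ = 0.994
U_SHIFT_MS = 0.288
U_SUPPORT_MS = (-0.215, 2.785)


def unitary_response(t_ms) -> np.ndarray:
    """Unitary extracellular waveform (uV) of one spike at t = 0."""
    t = np.asarray(t_ms, dtype=float)
    tau = t - U_SHIFT_MS
    u = U_AMP_UV * np.exp(-U_K_PER_MS * tau) * np.sin(2.0 * np.pi * U_F_KHZ * tau)
    out = np.where((t >= U_SUPPORT_MS[0]) & (t <= U_SUPPORT_MS[1]), u, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class CAPWaveform:
    """A CAP (or trial-averaged CAP) on a uniform time grid."""

    times: np.ndarray      # ms
    voltage: np.ndarray    # uV
    n_trials: int = 1

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def compute_cap(
    spike_trains,
    dt: float,
    t_max: float,
    t_min: float = 0.0,
    scale: float = 1.0,
) -> CAPWaveform:
    """Sum unitary responses of all spikes of all trains onto one grid.

    ``scale`` multiplies the waveform; it is used to report a
    subsampled population on the scale of the full one.
    """
    times = np.arange(t_min, t_max + dt / 2, dt)
    all_spikes = (
        np.concatenate([np.asarray(s, dtype=float) for s in spike_trains])
        if len(spike_trains)
        else np.empty(0)
    )
    v = np.zeros_like(times)
    if all_spikes.size:
        # bin spikes on the grid, then convolve once with sampled U
        lo, hi = U_SUPPORT_MS
        n_pre = int(np.ceil(-lo / dt)) + 1
        n_post = int(np.ceil(hi / dt)) + 1
        kernel_t = np.arange(-n_pre, n_post + 1) * dt
        kernel = unitary_response(kernel_t)
        idx = np.rint((all_spikes - t_min) / dt).astype(np.int64)
        counts = np.bincount(
            idx[(idx >= 0) & (idx < times.size)], minlength=times.size
        ).astype(float)
        v = np.convolve(counts, kernel, mode="full")[n_pre:n_pre + times.size]
    return CAPWaveform(times=times, voltage=v * scale)


def average_caps(waveforms) -> CAPWaveform:
    """Pointwise average of same-grid CAP waveforms."""
    if not len(waveforms):
        raise ValueError("no waveforms to average")
    t0 = waveforms[0].times
    for w in waveforms:
        if w.times.size != t0.size or abs(w.times[0] - t0[0]) > 1e-12:
            raise ValueError("waveforms must share one time grid")
    v = np.mean([w.voltage for w in waveforms], axis=0)
    return CAPWaveform(times=t0.copy(), voltage=v, n_trials=len(waveforms))


@dataclass
class CAPMetrics:
    amplitude_uV: float
    latency_ms: float
    width_ms: float
    peak_uV: float
    baseline_uV: float
    t_peak_ms: float
    t_half_ms: float


def measure_cap(
    cap: CAPWaveform,
    t_start: float,
    baseline_window_ms: float = 1.0,
    min_snr: float = 3.0,
) -> CAPMetrics:
    """Peak metrics of an averaged CAP.

    The baseline is the mean voltage over ``baseline_window_ms``
    preceding stimulus onset ``t_start``.  The first peak is the
    earliest local minimum after onset (matching the negative leading
    polarity of U) deflecting more than ``min_snr`` pre-stimulus
    standard deviations below baseline; for noise-free waveforms the
    SD guard degrades gracefully to an absolute floor.
    """
    t, v = cap.times, cap.voltage
    pre = (t >= t_start - baseline_window_ms) & (t < t_start)
    if not pre.any():
        pre = t < t_start
    if pre.any():
        b = float(v[pre].mean())
        noise = float(v[pre].std())
    else:
        # stimulus starts at the grid origin: no pre-stimulus window
        b, noise = 0.0, 0.0
    # guard against both pre-stimulus noise and minor pre-N1 ripples:
    # a candidate peak must deflect below baseline by > min_snr pre-SD
    # and by > 10% of the deepest post-onset deflection
    depth = float(np.maximum(b - v[t >= t_start], 0.0).max(initial=0.0))
    floor = max(min_snr * noise, 0.1 * depth, 1e-9)

    after = np.flatnonzero(t >= t_start)
    # local minima strictly below the detection floor
    inner = np.arange(1, t.size - 1)
    is_min = (v[inner] <= v[inner - 1]) & (v[inner] <= v[inner + 1])
    cand = inner[is_min & (v[inner] < b - floor) & (inner >= after[0])]
    if cand.size == 0:
        raise ValueError("flat waveform: no detectable CAP peak")
    ip = int(cand[0])
    # refine peak position by quadratic interpolation
    denom = v[ip - 1] - 2 * v[ip] + v[ip + 1]
    if denom != 0:
        shift = -0.5 * (v[ip + 1] - v[ip - 1]) / denom
        t_p = float(t[ip] + shift * cap.dt)
        p = float(v[ip] - 0.25 * (v[ip + 1] - v[ip - 1]) * shift)
    else:
        t_p, p = float(t[ip]), float(v[ip])

    a = abs(p - b)
    half_level = -(abs(b) + a / 2.0)
    # last crossing of the half level before the peak
    before = np.flatnonzero((t < t_p) & (v > half_level))
    if before.size == 0 or before[-1] + 1 >= t.size:
        t_w = t_p
    else:
        i = int(before[-1])
        frac = (half_level - v[i]) / (v[i + 1] - v[i])
        t_w = float(t[i] + frac * cap.dt)
    w = 2.0 * abs(t_p - t_w)
    return CAPMetrics(
        amplitude_uV=a,
        latency_ms=t_p - t_start,
        width_ms=w,
        peak_uV=p,
        baseline_uV=b,
        t_peak_ms=t_p,
        t_half_ms=t_w,
    )


def average_and_measure(waveforms, t_start: float, **kwargs) -> CAPMetrics:
    """Average trial CAPs, then measure the averaged waveform."""
    return measure_cap(average_caps(waveforms), t_start=t_start, **kwargs)


@dataclass
class IntervalHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray           # reflected, symmetric about 0
    intervals: np.ndarray        # signed intervals after reflection
    n_pairs: int                 # ordered train pairs tallied

    @property
    def sd(self) -> float:
        """SD of the pairwise-interval distribution (ms)."""
        if self.intervals.size == 0:
            return float("nan")
        return float(np.sqrt(np.mean(self.intervals**2)))

    def normalized(self, norm_constant: float | None = None) -> np.ndarray:
        """Counts normalized by ``norm_constant`` (default: own peak bin)."""
        if norm_constant is None:
            norm_constant = self.counts.max() if self.counts.size else 1.0
        return self.counts / max(norm_constant, 1)


def pairwise_interval_histogram(
    spike_trains,
    bin_width: float = 0.05,
    t_range: float | None = None,
) -> IntervalHistogram:
    """Forward intervals between every ordered pair of distinct trains.

    For each ordered pair (1, 2) and each spike i of train 1, the
    intervals to all spikes of train 2 falling in (t_i, t_{i+1}) are
    tallied (for the last spike the window extends to infinity).  The
    tally is then reflected about zero, since a forward interval of the
    pair (a, b) is a backward interval of (b, a).
    """
    trains = [np.sort(np.asarray(s, dtype=float)) for s in spike_trains]
    if len(trains) < 2:
        raise ValueError("need at least 2 spike trains")
    fwd = []
    n_pairs = 0
    for i1, t1 in enumerate(trains):
        for i2, t2 in enumerate(trains):
            if i1 == i2:
                continue
            n_pairs += 1
            if t1.size == 0 or t2.size == 0:
                continue
            # left-inclusive: a coincident spike of train 2 counts as a
            # zero interval
            nxt = np.append(t1[1:], np.inf)
            lo = np.searchsorted(t2, t1, side="left")
            hi = np.searchsorted(t2, nxt, side="left")
            for k in range(t1.size):
                if hi[k] > lo[k]:
                    fwd.append(t2[lo[k]:hi[k]] - t1[k])
    fwd = np.concatenate(fwd) if fwd else np.empty(0)
    intervals = np.concatenate([fwd, -fwd])
    if t_range is None:
        t_range = max(1.0, float(np.abs(intervals).max()) if intervals.size else 1.0)
    n_bins = int(np.ceil(t_range / bin_width))
    edges = np.arange(-n_bins, n_bins + 1) * bin_width
    counts, _ = np.histogram(intervals, bins=edges)
    return IntervalHistogram(
        bin_edges=edges, counts=counts.astype(float),
        intervals=intervals, n_pairs=n_pairs,
    )


def spike_probability(release_trains, spike_trains) -> float:
    """Mean spikes-per-release over fibers with at least one release."""
    ratios = []
    for rel, spk in zip(release_trains, spike_trains, strict=True):
        n_rel = len(rel)
        if n_rel > 0:
            ratios.append(len(spk) / n_rel)
    if not ratios:
        raise ValueError("no fiber received any release")
    return float(np.mean(ratios))


def spike_latency_stats(release_trains, spike_trains):
    """Mean and SD (ms) of spike minus most-recent-preceding-release.

    Pooled over all spikes of the population; spikes with no preceding
    release on their fiber are skipped.
    """
    lats = []
    for rel, spk in zip(release_trains, spike_trains, strict=True):
        rel = np.sort(np.asarray(rel, dtype=float))
        if rel.size == 0:
            continue
        for s in np.asarray(spk, dtype=float):
            i = np.searchsorted(rel, s, side="right") - 1
            if i >= 0:
                lats.append(s - rel[i])
    if not lats:
        raise ValueError("no spikes with a preceding release")
    lats = np.asarray(lats)
    return float(lats.mean()), float(lats.std())


@dataclass
class ScenarioComparison:
    mean_a: float
    mean_b: float
    difference: float
    percent_of_control: float
    se_difference: float
    p_value: float
    n_a: int
    n_b: int


def compare_scenarios(samples_a, samples_b) -> ScenarioComparison:
    """Welch two-sample comparison of replicate metric values.

    ``samples_a`` is the test scenario, ``samples_b`` the control; the
    percent-of-control difference is 100 * (mean_a - mean_b) / mean_b.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per scenario")
    diff = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ScenarioComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=diff,
        percent_of_control=100.0 * diff / b.mean(),
        se_difference=se,
        p_value=p,
        n_a=a.size,
        n_b=b.size,
    )
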