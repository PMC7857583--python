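import numpy as np
import pytest

from hhlsim.capx import (
    CAPWaveform,
    average_caps,
    compare_scenarios,
    compute_cap,
    measure_cap,
    pairwise_interval_histogram,
    spike_latency_stats,
    spike_probability,
    unitary_response,
)

DT = 0.005


class TestUnitaryResponse:
    def test_zero_at_the_phase_reference(self):
        assert unitary_response(0.288) == pytest.approx(0.0, abs=1e-12)

    def test_zero_outside_support(self):
        assert unitary_response(3.0) == 0.0
        assert unitary_response(-0.3) == 0.0

    def test_quarter_period_value(self):
        t = 0.288 + 1.0 / (4.0 * 0.994)
        expect = 0.16 * np.exp(-1.44 * 0.2515)
        assert unitary_response(t) == pytest.approx(expect, rel=1e-3)
        assert unitary_response(t) == pytest.approx(0.1113, abs=2e-4)

    def test_leading_deflection_is_negative(self):
        t = np.linspace(-0.215, 2.785, 3001)
        u = unitary_response(t)
        first_extreme = t[np.argmax(np.abs(u) > 0.5 * np.abs(u).max())]
        assert u[t <= first_extreme + 1e-9][-1] < 0


class TestComputeCAP:
    def test_no_spikes_zero_waveform(self):
        cap = compute_cap([[], []], dt=DT, t_max=5.0)
        assert np.all(cap.voltage == 0.0)

    def test_single_spike_reproduces_shifted_unitary_response(self):
        t0 = 2.0
        cap = compute_cap([[t0]], dt=DT, t_max=6.0)
        expect = unitary_response(cap.times - t0)
        np.testing.assert_allclose(cap.voltage, expect, atol=1e-9)

    def test_additivity_over_disjoint_spike_sets(self):
        a = [[1.0, 2.5], [3.0]]
        b = [[1.7], [2.2, 4.0]]
        cap_a = compute_cap(a, dt=DT, t_max=8.0)
        cap_b = compute_cap(b, dt=DT, t_max=8.0)
        cap_ab = compute_cap(a + b, dt=DT, t_max=8.0)
        np.testing.assert_allclose(
            cap_ab.voltage, cap_a.voltage + cap_b.voltage, atol=1e-12
        )

    def test_amplitude_scales_linearly_with_population_size(self, rng):
        spikes = [rng.normal(2.0, 0.2, size=3) for _ in range(50)]
        cap1 = compute_cap(spikes, dt=DT, t_max=6.0)
        cap2 = compute_cap(spikes + spikes, dt=DT, t_max=6.0)
        np.testing.assert_allclose(cap2.voltage, 2 * cap1.voltage, atol=1e-12)

    def test_scale_factor_for_subsampled_populations(self):
        cap = compute_cap([[1.0]], dt=DT, t_max=4.0, scale=10.0)
        expect = 10.0 * unitary_response(cap.times - 1.0)
        np.testing.assert_allclose(cap.voltage, expect, atol=1e-9)


def _triangle_cap(t_p=2.5, depth=-70.0, base_ms=1.0, t_max=6.0):
    t = np.arange(0.0, t_max + DT / 2, DT)
    v = np.zeros_like(t)
    half = base_ms / 2.0
    tri = np.abs(t - t_p) < half
    v[tri] = depth * (1.0 - np.abs(t[tri] - t_p) / half)
    return CAPWaveform(times=t, voltage=v)


class TestMeasureCAP:
    def test_amplitude_from_zero_baseline(self):
        m = measure_cap(_triangle_cap(), t_start=1.0)
        assert m.amplitude_uV == pytest.approx(70.0, rel=1e-3)
        assert m.baseline_uV == pytest.approx(0.0, abs=1e-9)

    def test_latency_relative_to_stimulus_onset(self):
        m = measure_cap(_triangle_cap(t_p=2.5), t_start=1.0)
        assert m.latency_ms == pytest.approx(1.5, abs=2 * DT)
        m0 = measure_cap(_triangle_cap(t_p=2.5), t_start=0.0)
        assert m0.latency_ms == pytest.approx(2.5, abs=2 * DT)

    def test_half_amplitude_width_of_triangle(self):
        # base 1 ms triangle: half-amplitude crossing 0.25 ms before the
        # peak, width = 2 * 0.25 = 0.5 ms
        m = measure_cap(_triangle_cap(), t_start=1.0)
        assert m.width_ms == pytest.approx(0.5, abs=4 * DT)

    def test_origin_shift_invariance(self):
        m1 = measure_cap(_triangle_cap(t_p=2.5), t_start=1.0)
        shifted = _triangle_cap(t_p=3.5, t_max=7.0)
        shifted.times = shifted.times
        m2 = measure_cap(shifted, t_start=2.0)
        assert m1.latency_ms == pytest.approx(m2.latency_ms, abs=1e-9)
        assert m1.amplitude_uV == pytest.approx(m2.amplitude_uV, rel=1e-9)

    def test_flat_waveform_is_an_error(self):
        t = np.arange(0.0, 5.0, DT)
        cap = CAPWaveform(times=t, voltage=np.zeros_like(t))
        with pytest.raises(ValueError):
            measure_cap(cap, t_start=1.0)

    def test_average_caps_requires_common_grid(self):
        a = _triangle_cap(t_max=6.0)
        b = _triangle_cap(t_max=7.0)
        with pytest.raises(ValueError):
            average_caps([a, b])


def _brute_force_intervals(trains):
    """All-pairs enumeration oracle of the forward-interval rule."""
    out = []
    for i, t1 in enumerate(trains):
        for j, t2 in enumerate(trains):
            if i == j:
                continue
            t1s = sorted(t1)
            for k, s in enumerate(t1s):
                nxt = t1s[k + 1] if k + 1 < len(t1s) else np.inf
                for u in t2:
                    if s <= u < nxt:
                        out.append(u - s)
    out = np.array(out)
    return np.concatenate([out, -out])


class TestIntervalHistogram:
    def test_identical_single_spikes_have_zero_sd(self):
        h = pairwise_interval_histogram([[1.0], [1.0], [1.0]])
        assert h.sd == pytest.approx(0.0)

    def test_two_trains_offset_by_delta(self):
        delta = 0.3
        h = pairwise_interval_histogram([[1.0], [1.0 + delta]])
        assert sorted(h.intervals.tolist()) == pytest.approx(
            [-delta, delta]
        )
        assert h.sd == pytest.approx(delta)

    def test_histogram_reflection_symmetry(self, rng):
        trains = [np.sort(rng.uniform(0, 10, size=8)) for _ in range(4)]
        h = pairwise_interval_histogram(trains, bin_width=0.25)
        np.testing.assert_array_equal(h.counts, h.counts[::-1])

    def test_matches_brute_force_oracle_exactly(self, rng):
        trains = [
            np.sort(rng.uniform(0, 5, size=rng.integers(1, 6)))
            for _ in range(5)
        ]
        h = pairwise_interval_histogram(trains)
        expect = _brute_force_intervals(trains)
        assert np.allclose(
            np.sort(h.intervals), np.sort(expect), atol=1e-12
        )

    def test_needs_two_trains(self):
        with pytest.raises(ValueError):
            pairwise_interval_histogram([[1.0]])


class TestSpikeStatistics:
    def test_probability_one_when_every_release_spikes(self):
        rel = [[1.0, 2.0], [1.5]]
        spk = [[1.4, 2.4], [1.9]]
        assert spike_probability(rel, spk) == pytest.approx(1.0)

    def test_probability_zero_without_spikes(self):
        assert spike_probability([[1.0]], [[]]) == 0.0

    def test_probability_ignores_fibers_without_releases(self):
        rel = [[1.0, 2.0], []]
        spk = [[1.4], []]
        assert spike_probability(rel, spk) == pytest.approx(0.5)

    def test_probability_error_when_no_releases_at_all(self):
        with pytest.raises(ValueError):
            spike_probability([[], []], [[], []])

    def test_latency_matches_most_recent_release(self):
        mean, sd = spike_latency_stats([[0.0]], [[0.9]])
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(0.0)

    def test_latency_pools_over_population(self):
        rel = [[0.0, 2.0], [1.0]]
        spk = [[0.5, 2.3], [1.2]]
        mean, sd = spike_latency_stats(rel, spk)
        assert mean == pytest.approx(np.mean([0.5, 0.3, 0.2]))


class TestCompareScenarios:
    def test_identical_samples_no_difference(self):
        c = compare_scenarios([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert c.difference == 0.0
        assert c.percent_of_control == 0.0

    def test_separated_samples_small_p(self):
        c = compare_scenarios([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert c.difference == pytest.approx(-1.0)
        assert c.p_value < 0.05
        assert c.percent_of_control == pytest.approx(-50.0)

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            compare_scenarios([1.0], [2.0, 3.0])
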