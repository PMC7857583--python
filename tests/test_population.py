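import numpy as np
import pytest

from hhlsim.population import (
    CONTROL_LH_UM,
    CONTROL_LU_UM,
    FiberSpec,
    PopulationRunner,
    apply_myelinopathy,
    apply_synaptopathy,
    build_population,
    make_scenario,
)
from hhlsim.stimulus import SoundStimulus


def _stim(level=70.0):
    return SoundStimulus(frequency=10e3, level=level, duration=5.0,
                         onset_time=1.0, total_sim_time=9.0)


class TestBuildPopulation:
    def test_default_control_population(self):
        specs = build_population()
        assert len(specs) == 6300
        assert all(s.L_u == CONTROL_LU_UM for s in specs)
        assert all(s.L_h == CONTROL_LH_UM for s in specs)
        assert all(s.synapse_present for s in specs)
        # unique, sequential ids
        assert sorted(s.fiber_id for s in specs) == list(range(6300))

    def test_composition_per_best_frequency(self):
        specs = build_population(n_bfs=3, n_per_type=10)
        bfs = sorted({s.bf_hz for s in specs})
        assert len(bfs) == 3
        for bf in bfs:
            here = [s for s in specs if s.bf_hz == bf]
            for ftype in ("LT", "MT", "HT"):
                assert sum(s.fiber_type == ftype for s in here) == 10

    def test_empty_population_warns(self):
        with pytest.warns(UserWarning):
            specs = build_population(n_bfs=0)
        assert specs == []


class TestMyelinopathy:
    def test_heterogeneous_lu_draws_in_range(self, rng):
        specs = build_population(n_bfs=2, n_per_type=20)
        out = apply_myelinopathy(
            specs, "heterogeneous_Lu", rng, fraction_increase=1.0
        )
        lus = np.array([s.L_u for s in out])
        assert np.all((lus >= 10.0) & (lus <= 20.0))
        assert lus.std() > 0

    def test_homogeneous_control_value_is_identity(self, rng):
        specs = build_population(n_bfs=1, n_per_type=5)
        out = apply_myelinopathy(specs, "homogeneous_Lu", rng, L_u=10.0)
        assert [s.L_u for s in out] == [s.L_u for s in specs]

    def test_reproducible_under_fixed_seed(self):
        specs = build_population(n_bfs=1, n_per_type=30)
        a = apply_myelinopathy(
            specs, "heterogeneous_both", np.random.default_rng(42)
        )
        b = apply_myelinopathy(
            specs, "heterogeneous_both", np.random.default_rng(42)
        )
        assert [(s.L_u, s.L_h) for s in a] == [(s.L_u, s.L_h) for s in b]

    def test_below_control_rejected(self, rng):
        specs = build_population(n_bfs=1, n_per_type=2)
        with pytest.raises(ValueError):
            apply_myelinopathy(specs, "homogeneous_Lu", rng, L_u=8.0)
        with pytest.raises(ValueError):
            apply_myelinopathy(specs, "not_a_mode", rng)

    def test_specs_never_deleted(self, rng):
        specs = build_population(n_bfs=2, n_per_type=7)
        out = apply_myelinopathy(specs, "heterogeneous_Lh", rng)
        assert len(out) == len(specs)


class TestSynaptopathy:
    def test_ht_mode_removes_exactly_the_ht_third(self, rng):
        specs = build_population(n_bfs=21, n_per_type=100)
        out = apply_synaptopathy(specs, "HT", rng)
        removed = [s for s in out if not s.synapse_present]
        assert len(removed) == 2100
        assert all(s.fiber_type == "HT" for s in removed)

    def test_random_third_spreads_over_types(self, rng):
        specs = build_population(n_bfs=21, n_per_type=100)
        out = apply_synaptopathy(specs, "random_third", rng)
        removed = [s for s in out if not s.synapse_present]
        assert len(removed) == 2100
        per_type = {
            t: sum(s.fiber_type == t for s in removed)
            for t in ("LT", "MT", "HT")
        }
        # uniform sampling: ~700 each, allow 4 sigma of hypergeometric
        for n in per_type.values():
            assert abs(n - 700) < 4 * np.sqrt(2100 * (1 / 3) * (2 / 3))

    def test_morphology_untouched(self, rng):
        specs = build_population(n_bfs=1, n_per_type=10)
        out = apply_synaptopathy(specs, "HT", rng)
        assert [(s.L_u, s.L_h) for s in out] == [
            (s.L_u, s.L_h) for s in specs
        ]


class TestScenarios:
    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            make_scenario("nope", _stim())

    def test_case3_combines_lesions(self):
        sc = make_scenario("case3", _stim(), n_bfs=2, n_per_type=6,
                           master_seed=5)
        lus = np.array([s.L_u for s in sc.specs])
        assert lus.max() > 10.0
        masked = [s for s in sc.specs if not s.synapse_present]
        assert masked and all(s.fiber_type == "HT" for s in masked)

    def test_lesion_draws_depend_only_on_master_seed(self):
        a = make_scenario("het_lu", _stim(), n_bfs=1, n_per_type=10,
                          master_seed=3, n_trials=1)
        b = make_scenario("het_lu", _stim(), n_bfs=1, n_per_type=10,
                          master_seed=3, n_trials=50)
        assert [s.L_u for s in a.specs] == [s.L_u for s in b.specs]

    def test_scale_to_full_population(self):
        sc = make_scenario("control", _stim(), n_bfs=21, n_per_type=10)
        assert sc.scale_to_full == pytest.approx(10.0)


class TestTrials:
    @pytest.fixture(scope="class")
    def small_result(self):
        sc = make_scenario("control", _stim(), n_bfs=3, n_per_type=2,
                           master_seed=11)
        runner = PopulationRunner(sc)
        return sc, runner, runner.run_trial(0)

    def test_trial_is_deterministic(self, small_result):
        sc, runner, res = small_result
        res2 = PopulationRunner(sc).run_trial(0)
        for a, b in zip(res.spike_trains, res2.spike_trains, strict=True):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(res.release_trains, res2.release_trains,
                        strict=True):
            np.testing.assert_array_equal(a, b)

    def test_different_trials_differ(self, small_result):
        sc, runner, res = small_result
        res2 = runner.run_trial(1)
        same = all(
            np.array_equal(a, b)
            for a, b in zip(res.release_trains, res2.release_trains)
        )
        assert not same

    def test_masked_fibers_stay_silent(self):
        sc = make_scenario("synaptopathy_ht", _stim(), n_bfs=2,
                           n_per_type=3, master_seed=2)
        res = PopulationRunner(sc).run_trial(0)
        for spec, rel, spk in zip(
            sc.specs, res.release_trains, res.spike_trains, strict=True
        ):
            if not spec.synapse_present:
                assert rel.size == 0 and spk.size == 0

    def test_spikes_follow_releases(self, small_result):
        sc, runner, res = small_result
        for rel, spk in zip(res.release_trains, res.spike_trains,
                            strict=True):
            if spk.size:
                assert rel.size > 0
                assert spk.min() >= rel.min()
            if spk.size > 1:
                assert np.all(np.diff(spk) >= 0.7 - 1e-9)
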