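"""Unit and property tests for the digital-ecology simulator."""

import numpy as np
import pytest
from scipy import stats

from phyloerosion import (
    CullError,
    EcologyConfig,
    TreatmentSchedule,
    apply_pulse_cull,
    init_state,
    make_schedule,
    profile_config,
    run_experiment,
    set_press_inflows,
    step_update,
)

from conftest import SUITE_SEED


def quiet_config(**over):
    """Small config with no births/mutations unless overridden."""
    base = dict(population_size=4, birth_rate=0.0, mu_trait=0.0, mu_tag=0.0,
                mu_lethal=0.0)
    base.update(over)
    return EcologyConfig(**base)


class TestResourceDynamics:
    def test_unconsumed_pools_converge_to_inflow_over_decay(self):
        """With no performers, each pool approaches the fixed point I/delta
        of C <- (1-delta) C + I."""
        cfg = quiet_config(decay=0.1)
        pop, res = init_state(cfg)
        rng = np.random.default_rng(0)
        for _ in range(500):
            step_update(pop, res, cfg, rng)
        expected = np.asarray(cfg.inflow) / cfg.decay
        assert np.allclose(res.concentrations, expected, atol=1e-6)

    def test_single_performer_merit_matches_hand_iteration(self):
        """Two-update hand oracle: one organism bearing the first basal trait
        gets per-update merit base_merit + reward * alpha * C with C depressed
        by its own consumption."""
        cfg = quiet_config(decay=0.05, uptake_fraction=0.2)
        pop, res = init_state(cfg)
        pop.traits[0, 0] = 1.0
        pop.n_traits[0] = 1
        rng = np.random.default_rng(0)

        inflow, delta, alpha = cfg.inflow[0], cfg.decay, cfg.uptake_fraction
        reward = cfg.rewards[0]
        # hand iteration, update 1: C = 0*(1-d) + I; consume alpha*C
        c = inflow
        merit1 = reward * alpha * c
        c = c * (1 - alpha)
        # update 2
        c = c * (1 - delta) + inflow
        merit2 = reward * alpha * c

        step_update(pop, res, cfg, rng)
        assert cfg.base_merit + pop.merit[0] == pytest.approx(
            cfg.base_merit + merit1
        )
        step_update(pop, res, cfg, rng)
        assert pop.merit[0] == pytest.approx(merit2)
        assert res.concentrations.min() >= 0

    def test_press_scales_organism_free_equilibrium_exactly(self):
        cfg = EcologyConfig()
        pressed = set_press_inflows(cfg, 0.01)
        assert pressed.inflow[0] == pytest.approx(cfg.inflow[0] * 0.01)
        # organism-free equilibrium I/delta scales by exactly the factor
        eq = np.asarray(cfg.inflow) / cfg.decay
        eq_pressed = np.asarray(pressed.inflow) / pressed.decay
        assert np.allclose(eq_pressed, 0.01 * eq)
        weak = set_press_inflows(cfg, 0.1)
        assert weak.inflow[1] == pytest.approx(cfg.inflow[1] * 0.1)
        assert set_press_inflows(cfg, 1.0) == cfg

    @pytest.mark.parametrize("factor", [0.0, -0.5])
    def test_nonpositive_press_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            set_press_inflows(EcologyConfig(), factor)


class TestGenealogyBookkeeping:
    def test_zero_mutation_rates_keep_single_founder_genotype(self):
        cfg = quiet_config(population_size=50, birth_rate=0.2)
        pop, res = init_state(cfg)
        rng = np.random.default_rng(1)
        for _ in range(200):
            step_update(pop, res, cfg, rng)
        assert len(pop.log) == 1
        assert pop.n_alive == 50

    def test_population_size_and_counts_invariants(self):
        cfg = profile_config("desk")
        pop, res = init_state(cfg)
        rng = np.random.default_rng(2)
        for _ in range(300):
            step_update(pop, res, cfg, rng)
            assert pop.n_alive == cfg.population_size
            assert res.concentrations.min() >= 0
        # log-derived extant set matches the population census
        census = np.unique(pop.genotype[pop.alive])
        assert np.array_equal(pop.log.extant_at(pop.update), census)


class TestPulseCull:
    @pytest.mark.parametrize("survivors", [4, 36])
    def test_cull_leaves_exactly_the_survivor_count(self, survivors):
        cfg = quiet_config(population_size=3600)
        pop, _ = init_state(cfg)
        rng = np.random.default_rng(3)
        apply_pulse_cull(pop, survivors, rng)
        assert pop.n_alive == survivors
        assert pop.viable[pop.alive].all()

    def test_identity_cull_preserves_population_multiset(self):
        cfg = profile_config("desk")
        pop, res = init_state(cfg)
        rng = np.random.default_rng(4)
        for _ in range(50):
            step_update(pop, res, cfg, rng)
        viable = int((pop.alive & pop.viable).sum())
        before = np.sort(pop.genotype[pop.alive & pop.viable])
        apply_pulse_cull(pop, viable, rng)
        assert np.array_equal(np.sort(pop.genotype[pop.alive]), before)

    def test_cull_with_too_few_viable_organisms_fails(self):
        cfg = quiet_config(population_size=10)
        pop, _ = init_state(cfg)
        with pytest.raises(CullError):
            apply_pulse_cull(pop, 11, np.random.default_rng(0))

    def test_cull_survivors_drawn_from_viable_only(self):
        cfg = quiet_config(population_size=20)
        pop, _ = init_state(cfg)
        pop.viable[:15] = False
        rng = np.random.default_rng(5)
        apply_pulse_cull(pop, 5, rng)
        assert set(np.flatnonzero(pop.alive)) <= set(range(15, 20))


class TestRunExperiment:
    def test_control_bookkeeping_and_snapshots(self):
        cfg = profile_config("desk")
        sched = make_schedule("control", "desk", pre_updates=500,
                              press_duration=100, recovery_updates=500,
                              sampling_offsets=(0, 100, 500))
        result = run_experiment(cfg, sched, seed=SUITE_SEED)
        assert not result.failed
        assert set(result.snapshots) == {"pre", "rec_0", "rec_100", "rec_500"}
        assert result.snapshots["pre"].update == 500
        assert result.snapshots["rec_500"].update == sched.total_updates
        ext = np.asarray(result.log.extinction)
        assert ext.max() <= sched.total_updates

    def test_same_seed_yields_bit_identical_genealogy(self, tmp_path):
        cfg = profile_config("desk")
        sched = make_schedule("pulse-strong", "desk", pre_updates=400,
                              recovery_updates=300, sampling_offsets=(0, 300))
        a = run_experiment(cfg, sched, seed=99)
        b = run_experiment(cfg, sched, seed=99)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.log.to_tsv(pa)
        b.log.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = run_experiment(cfg, sched, seed=100)
        assert len(c.log) != len(a.log) or not (
            np.asarray(c.log.origin) == np.asarray(a.log.origin)
        ).all()

    def test_pulse_experiment_snapshots_reflect_survivor_census(self):
        cfg = profile_config("desk")
        sched = make_schedule("pulse-strong", "desk", pre_updates=400,
                              recovery_updates=200, sampling_offsets=(0, 200))
        result = run_experiment(cfg, sched, seed=7)
        post = result.snapshots["rec_0"]
        assert post.n_organisms == 4
        assert len(post.genotypes) <= 4
        # survivors are a subset of the pre-extinction extant genotypes
        pre = result.snapshots["pre"]
        assert set(post.genotypes) <= set(pre.genotypes)

    def test_press_selectivity_strips_trait_bearing_genotypes(self):
        """Across seeded replicates of a short strong press, the number of
        distinct trait-bearing genotypes falls during the episode (the
        emergent disaster-taxa effect), one-sided sign test p < 0.05."""
        cfg = profile_config("desk")
        sched = make_schedule("press-strong", "desk", pre_updates=5000,
                              press_duration=500, recovery_updates=0,
                              sampling_offsets=(0,))
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            result = run_experiment(cfg, sched, seed=SUITE_SEED + seed)
            n_traits = np.asarray(result.log.n_traits)
            start = result.snapshots["pre"].genotypes
            end = result.snapshots["rec_0"].genotypes
            if (n_traits[end] > 0).sum() < (n_traits[start] > 0).sum():
                wins += 1
        p = stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
        assert p < 0.05


class TestConfigValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EcologyConfig(population_size=1)
        with pytest.raises(ValueError):
            EcologyConfig(decay=0.0)
        with pytest.raises(ValueError):
            EcologyConfig(mu_trait=1.5)
        with pytest.raises(ValueError):
            EcologyConfig(rewards=(1.0,) * 8)
        with pytest.raises(ValueError):
            TreatmentSchedule(kind="pulse", pulse_survivors=1)
        with pytest.raises(ValueError):
            TreatmentSchedule(kind="press", press_inflow_factor=0.0)
        with pytest.raises(ValueError):
            TreatmentSchedule(kind="control", sampling_offsets=(10, 5))

    def test_yaml_round_trip(self, tmp_path):
        from phyloerosion import load_config, save_config

        cfg = profile_config("desk", mu_tag=0.03)
        sched = make_schedule("press-weak", "desk")
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path, schedule=sched)
        cfg2, sched2 = load_config(path)
        assert cfg2 == cfg
        assert sched2 == sched
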