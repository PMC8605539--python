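import math

import numpy as np
import pytest

from grnmaps.development import DevelopmentParams
from grnmaps.ensemble import EnsembleConfig, build_ensemble
from grnmaps.evolution import (
    EvolutionConfig,
    GrainSchedule,
    Individual,
    evaluate_individual,
    evaluate_population,
    evolve,
    init_population,
    mutate,
    probe_nonselected_maps,
    select_reproduce,
)
from grnmaps.maps import Element

from .conftest import make_genome


@pytest.fixture
def evo_config(fast_params):
    return EvolutionConfig(
        pop_size=8,
        max_generations=30,
        grain=5,
        dev_params=fast_params,
        record_every=5,
    )


@pytest.fixture
def tiny_population(evo_config, rng):
    pairs = build_ensemble(EnsembleConfig(n_networks=40, seed=21, ng_max=6))
    return init_population(pairs, evo_config, rng)


class TestMutate:
    def test_rate_zero_identity(self, rng):
        g = make_genome(5, mask=np.ones((5, 5)), strengths=np.ones((5, 5)))
        cfg = EvolutionConfig(mutation_rate=0.0)
        out = mutate(g, cfg, rng)
        assert np.array_equal(out.topology_mask, g.topology_mask)
        assert np.array_equal(out.interaction_strengths, g.interaction_strengths)

    def test_expected_flip_count(self, rng):
        # N_g=10: expected flipped topology bits per call = 0.04 * 100 = 4
        g = make_genome(10)
        cfg = EvolutionConfig(mutation_rate=0.04)
        flips = []
        for _ in range(500):
            out = mutate(g, cfg, rng)
            flips.append(np.sum(out.topology_mask != g.topology_mask))
        assert np.mean(flips) == pytest.approx(4.0, abs=0.3)

    def test_perturbation_kernel_std(self, rng):
        # conditional on a hit, the B jitter is N(0, 0.01)
        g = make_genome(1, mask=[[1]], strengths=[[0.5]])
        cfg = EvolutionConfig(mutation_rate=1.0, mutation_sd=0.01)
        deltas = np.array(
            [mutate(g, cfg, rng).interaction_strengths[0, 0] - 0.5 for _ in range(5000)]
        )
        assert deltas.std() == pytest.approx(0.01, rel=0.1)
        assert abs(deltas.mean()) < 0.001

    def test_input_genome_unchanged(self, rng):
        g = make_genome(4, mask=np.ones((4, 4)), strengths=np.ones((4, 4)))
        before = g.interaction_strengths.copy()
        mutate(g, EvolutionConfig(mutation_rate=1.0), rng)
        assert np.array_equal(g.interaction_strengths, before)

    def test_z_mutated(self, rng):
        g = make_genome(3, model_kind="multilinear", z=np.zeros((2, 3)))
        out = mutate(g, EvolutionConfig(mutation_rate=1.0), rng)
        assert not np.array_equal(out.multilinear_coeffs, g.multilinear_coeffs)


class TestFitness:
    def _individual(self, fast_params):
        # single self-activating gene, traits read positively from it
        g = make_genome(
            2,
            mask=[[1, 0], [0, 0]],
            strengths=[[0.0, 0.0], [0.0, 0.0]],
            g0=[0.5, 0.0],
            model_kind="multilinear",
            z=[[1.0 - 1e-9, 0.0], [0.5, 0.0]],
        )
        from grnmaps.ensemble import EnvironmentVector

        return Individual(g, EnvironmentVector(np.zeros(2)), Element("B", 0, 0))

    def test_fitness_one_at_zero_error(self, fast_params):
        # T2 = 0.5 * T1 exactly, so S = 0.5; W = 1 when the target equals it
        ind = self._individual(fast_params)
        cfg = EvolutionConfig(target_slope=0.5, dev_params=fast_params)
        w, s, _ = evaluate_individual(ind, cfg, np.linspace(0.1, 1, 5))
        assert s == pytest.approx(0.5, abs=1e-6)
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_fitness_exp_decay(self, fast_params):
        # |S - S_T| = 0.5 gives W = e^{-0.5}
        ind = self._individual(fast_params)
        cfg = EvolutionConfig(target_slope=1.0, dev_params=fast_params)
        w, _, _ = evaluate_individual(ind, cfg, np.linspace(0.1, 1, 5))
        assert w == pytest.approx(math.exp(-0.5), abs=1e-4)

    def test_euclidean_mode_bounds(self, fast_params):
        ind = self._individual(fast_params)
        cfg = EvolutionConfig(target_slope=1.0, dev_params=fast_params, fitness_mode="euclidean")
        w, _, _ = evaluate_individual(ind, cfg, np.linspace(0.1, 1, 5))
        assert 0.0 < w < 1.0

    def test_too_few_viable_points_zero(self, fast_params):
        ind = self._individual(fast_params)
        cfg = EvolutionConfig(dev_params=fast_params)
        w, s, _ = evaluate_individual(ind, cfg, np.array([0.5]))
        assert w == 0.0 and s is None

    def test_population_batch_matches_individual(self, tiny_population, evo_config, rng):
        inputs = np.linspace(0.1, 1, 5)
        fb, _ = evaluate_population(tiny_population, evo_config, inputs)
        fi = np.array([evaluate_individual(ind, evo_config, inputs)[0] for ind in tiny_population])
        assert np.allclose(fb, fi)

    def test_fitness_bounds_property(self, tiny_population, evo_config, rng):
        for mode in ("slope", "euclidean"):
            evo_config.fitness_mode = mode
            f, _ = evaluate_population(tiny_population, evo_config, np.linspace(0.1, 1, 5))
            assert np.all(f >= 0) and np.all(f <= 1)


class TestSelectReproduce:
    def test_neutral_drift_mean_one(self, tiny_population, rng):
        fit = np.ones(len(tiny_population))
        offspring = select_reproduce(tiny_population, fit, rng)
        assert len(offspring) == len(tiny_population)

    def test_deterministic_sweep(self, tiny_population, rng):
        fit = np.zeros(len(tiny_population))
        fit[3] = 1.0
        offspring = select_reproduce(tiny_population, fit, rng)
        winner = tiny_population[3].genome.interaction_strengths
        for child in offspring:
            assert np.array_equal(child.genome.interaction_strengths, winner)

    def test_proportional_sampling_law(self, rng):
        pop = [
            Individual(make_genome(3), __import__("grnmaps.ensemble", fromlist=["EnvironmentVector"]).EnvironmentVector(np.zeros(3)), Element("G0", 0))
            for _ in range(2)
        ]
        counts = 0
        n = 3000
        fit = np.array([2.0, 1.0])
        chosen = rng.choice(2, size=n, p=fit / fit.sum())
        counts = np.sum(chosen == 0)
        assert abs(counts - 2 * n / 3) < 4 * np.sqrt(n * (2 / 3) * (1 / 3))

    def test_all_zero_fitness_uniform(self, tiny_population, rng):
        offspring = select_reproduce(tiny_population, np.zeros(len(tiny_population)), rng)
        assert len(offspring) == len(tiny_population)


class TestGrainSchedule:
    def test_grain_ten_fixed_grid(self, rng):
        sched = GrainSchedule(10, rng, fixed_grid=True)
        inputs = sched.inputs_for(0)
        assert len(inputs) == 10
        assert inputs[0] == pytest.approx(0.1) and inputs[-1] == pytest.approx(1.0)

    def test_grain_ten_random(self, rng):
        sched = GrainSchedule(10, rng, fixed_grid=False)
        a = sched.inputs_for(0)
        b = sched.inputs_for(1)
        assert len(a) == 10 and not np.array_equal(a, b)
        assert np.all(a > 0) and np.all(a <= 1)

    def test_grain_one_fresh_each_generation(self, rng):
        sched = GrainSchedule(1, rng, fixed_grid=False)
        assert len(sched.inputs_for(0)) == 1
        assert sched.inputs_for(0) != sched.inputs_for(1)

    def test_coarse_grain_held_between_redraws(self, rng):
        # grain 0.5: one input redrawn every 2 generations
        sched = GrainSchedule(0.5, rng)
        x0 = sched.inputs_for(0).copy()
        x1 = sched.inputs_for(1)
        assert np.array_equal(x0, x1)
        x2 = sched.inputs_for(2)
        assert not np.array_equal(x0, x2)

    def test_invalid_grain(self, rng):
        with pytest.raises(ValueError):
            GrainSchedule(0.0, rng)


class TestEvolve:
    def test_seeded_reproducibility(self, tiny_population, evo_config):
        r1 = evolve([i.copy() for i in tiny_population], evo_config, np.random.default_rng(5))
        r2 = evolve([i.copy() for i in tiny_population], evo_config, np.random.default_rng(5))
        assert np.array_equal(r1.mean_fitness, r2.mean_fitness)
        assert np.array_equal(
            r1.final_population[0].genome.interaction_strengths,
            r2.final_population[0].genome.interaction_strengths,
        )

    def test_absorbing_optimum(self, fast_params, rng):
        # mutation off, identical perfect-fitness genomes: trajectory constant at W=1
        g = make_genome(
            2,
            mask=[[1, 0], [0, 0]],
            g0=[0.5, 0.0],
            model_kind="multilinear",
            z=[[0.9, 0.0], [0.45, 0.0]],
        )
        from grnmaps.ensemble import EnvironmentVector

        pop = [Individual(g.copy(), EnvironmentVector(np.zeros(2)), Element("B", 0, 0)) for _ in range(4)]
        cfg = EvolutionConfig(
            pop_size=4,
            max_generations=10,
            mutation_rate=0.0,
            target_slope=0.5,
            dev_params=fast_params,
            convergence_window=1000,
        )
        run = evolve(pop, cfg, rng)
        assert np.allclose(run.mean_fitness, 1.0, atol=1e-6)

    def test_heritability_sanity(self, fast_params, rng):
        # mutation off, selection on: population converges to the best lineage
        pairs = build_ensemble(EnsembleConfig(n_networks=30, seed=77, ng_max=5))
        cfg = EvolutionConfig(
            pop_size=10,
            max_generations=60,
            mutation_rate=0.0,
            grain=5,
            dev_params=fast_params,
            convergence_window=10_000,
        )
        pop = init_population(pairs, cfg, rng)
        run = evolve(pop, cfg, rng)
        finals = run.final_population
        first = finals[0].genome.interaction_strengths
        assert all(
            np.array_equal(ind.genome.interaction_strengths, first) for ind in finals[1:]
        )

    def test_target_shift_fitness_drop(self, tiny_population, fast_params):
        cfg = EvolutionConfig(
            pop_size=len(tiny_population),
            max_generations=40,
            grain=5,
            target_slope=1.0,
            target_schedule=((20, -1.0),),
            dev_params=fast_params,
            convergence_window=10_000,
            record_every=1,
        )
        run = evolve(tiny_population, cfg, np.random.default_rng(8))
        w = dict(zip(run.generations.tolist(), run.mean_fitness.tolist()))
        # shifting the target perturbs mean fitness at the shift generation
        assert w[20] != pytest.approx(w[19], abs=1e-12)

    def test_max_generations_respected(self, tiny_population, evo_config):
        run = evolve(tiny_population, evo_config, np.random.default_rng(9))
        assert run.generations[-1] <= evo_config.max_generations - 1


class TestProbe:
    def test_probe_selected_kind_recovers_slopes(self, tiny_population, evo_config):
        rng = np.random.default_rng(10)
        probes = probe_nonselected_maps(
            tiny_population[:3], evo_config, rng, n_collapsed=1, kinds=("GP",)
        )
        assert len(probes["GP"]) == 3
        for rec in probes["GP"]:
            assert 0 < rec["collapsed_x"] <= 1

    def test_probe_returns_all_kinds(self, tiny_population, evo_config):
        rng = np.random.default_rng(11)
        probes = probe_nonselected_maps(tiny_population[:2], evo_config, rng, n_collapsed=1)
        assert set(probes) == {"GP", "EP", "PP"}
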