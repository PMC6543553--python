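"""Genetic-algorithm operators, evaluation determinism and the fitter."""

import numpy as np
import pytest

from strfnet.network import Genome
from strfnet.optimize import (
    EvalContext,
    GAConfig,
    GeneticNetworkFitter,
    cost_of,
    evaluate,
    evaluate_strf,
    init_population,
    next_generation,
    run_ga,
)
from strfnet.strf import cost, significance_mask

TINY = GAConfig(
    population=10, elite=2, parents=4, crossover=4, mutation=4, generations=2, seed=0
)


class TestGAConfig:
    def test_default_composition_is_40_480_480_of_1000(self):
        cfg = GAConfig()
        assert cfg.elite + cfg.crossover + cfg.mutation == cfg.population == 1000
        assert (cfg.elite, cfg.crossover, cfg.mutation) == (40, 480, 480)
        assert cfg.parents == 100

    def test_reduced_preset_composition(self):
        cfg = GAConfig.reduced()
        assert cfg.population == 60
        assert cfg.elite + cfg.crossover + cfg.mutation == 60

    def test_inconsistent_composition_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population=100, elite=10, crossover=50, mutation=50)


class TestInitPopulation:
    def test_counts_and_bounds_full_scale(self):
        pop = init_population(GAConfig(seed=1), 15)
        assert len(pop) == 1000
        flats = np.array([g.flat() for g in pop])
        assert flats.shape == (1000, 255)
        assert flats.min() >= -5 and flats.max() <= 5

    def test_seed_determinism(self):
        a = init_population(TINY, 5)
        b = init_population(TINY, 5)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.flat(), gb.flat())


class TestNextGeneration:
    def test_size_conserved_and_elite_verbatim(self):
        pop = init_population(TINY, 5)
        costs = np.arange(len(pop), dtype=float)[::-1]  # last is best
        new = next_generation(pop, costs, TINY, seed=0)
        assert len(new) == TINY.population
        order = np.argsort(costs, kind="stable")
        for k in range(TINY.elite):
            np.testing.assert_array_equal(new[k].flat(), pop[order[k]].flat())

    def test_crossover_genes_come_from_parents(self):
        cfg = GAConfig(
            population=8, elite=2, parents=2, crossover=3, mutation=3,
            generations=1, seed=0,
        )
        pop = init_population(cfg, 4)
        costs = np.arange(len(pop), dtype=float)
        new = next_generation(pop, costs, cfg, seed=5)
        p0, p1 = pop[0].flat(), pop[1].flat()
        for child in new[cfg.elite : cfg.elite + cfg.crossover]:
            c = child.flat()
            assert np.all((c == p0) | (c == p1))

    def test_gene_bounds_after_operators(self):
        pop = init_population(TINY, 5)
        costs = np.random.default_rng(0).random(len(pop))
        for seed in range(3):
            pop = next_generation(pop, costs, TINY, seed=seed)
            flats = np.array([g.flat() for g in pop])
            assert flats.min() >= -5 and flats.max() <= 5

    def test_population_smaller_than_parent_pool_rejected(self):
        pop = init_population(TINY, 5)[:3]
        with pytest.raises(ValueError):
            next_generation(pop, np.zeros(3), TINY, seed=0)


class TestEvaluate:
    def test_deterministic(self, small_ctx, small_gt):
        gt, target = small_gt
        assert evaluate(gt, target, small_ctx) == evaluate(gt, target, small_ctx)

    def test_ground_truth_cost_is_zero_with_generating_seeds(self, small_ctx, small_gt):
        gt, target = small_gt
        assert cost_of(gt, target, small_ctx, 2) == 0.0

    def test_zero_genome_cost_matches_direct_formula(self, small_ctx, small_gt):
        # no synapses and no tonic drive -> no spikes -> zero model STRF,
        # so the cost is sum(weights * |normalized target|)
        _, target = small_gt
        zero = Genome.zeros(5)
        c = cost_of(zero, target, small_ctx, 2)
        w = significance_mask(target).weights
        expected = np.sum(w * np.abs(target.values / np.abs(target.values).max()))
        assert c == pytest.approx(expected)

    def test_ground_truth_beats_most_single_gene_mutants(self, small_ctx, small_gt):
        gt, target = small_gt
        c0 = cost_of(gt, target, small_ctx, 2)
        rng = np.random.default_rng(1)
        flat = gt.flat()
        wins = 0
        n_mutants = 20
        for _ in range(n_mutants):
            g = rng.integers(len(flat))
            new = flat.copy()
            choices = [v for v in range(-5, 6) if v != flat[g]]
            new[g] = rng.choice(choices)
            cm = cost_of(Genome.from_flat(new, 5), target, small_ctx, 2)
            if c0 <= cm:
                wins += 1
        assert wins >= 0.9 * n_mutants


class TestRunGA:
    def test_history_non_increasing_and_result_consistent(self, small_ctx, small_gt):
        _, target = small_gt
        result = run_ga(target, TINY, small_ctx)
        hist = np.array(result.history_best)
        assert np.all(np.diff(hist) <= 0)
        assert result.best_cost == hist[-1] == hist.min()
        assert result.n_evaluations == TINY.population + TINY.generations * (
            TINY.population - TINY.elite
        )

    def test_final_costs_similar_across_seeds(self, small_ctx, small_gt):
        # different seeds find different genomes but comparable final costs
        _, target = small_gt
        cfg = GAConfig(
            population=20, elite=2, parents=5, crossover=9, mutation=9,
            generations=5,
        )
        from dataclasses import replace

        finals, genomes = [], []
        for seed in (0, 1, 2):
            res = run_ga(target, replace(cfg, seed=seed), small_ctx)
            finals.append(res.best_cost)
            genomes.append(tuple(res.best_genome.flat()))
        assert len(set(genomes)) > 1
        assert np.std(finals) / np.mean(finals) < 0.5


class TestGeneticNetworkFitter:
    def test_sklearn_estimator_contract(self, small_ctx, small_gt):
        _, target = small_gt
        fitter = GeneticNetworkFitter(
            population=10, elite=2, parents=4, crossover=4, mutation=4,
            generations=2, seed=0,
        )
        params = fitter.get_params()
        assert params["population"] == 10
        fitter.set_params(generations=1)
        fitter.fit(target, eval_ctx=small_ctx)
        assert hasattr(fitter, "best_genome_")
        predicted = fitter.predict()
        assert predicted.values.shape == target.values.shape
        assert fitter.score(target) == pytest.approx(-cost(predicted, target))

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            GeneticNetworkFitter().predict()
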