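import numpy as np
import pytest

import sdmkit as sk
from sdmkit.models import HyperCombo
from sdmkit.tuning import (
    Evaluated,
    GAConfig,
    HyperGrid,
    crossover,
    expected_trainings,
    grid_search,
    optimize_model,
    random_search,
    rank_fitness,
)

SMALL_GRID = HyperGrid("Maxent", {"fc": ["l", "lq"], "reg": [0.5, 1.0, 2.0]})


@pytest.fixture(scope="module")
def tuning_setup(species_pb):
    fold = sk.random_folds(species_pb, 2, seed=0)
    return species_pb, fold


class TestHyperGrid:
    def test_combination_count(self):
        assert SMALL_GRID.n_combinations == 6

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid("Maxent", {"reg": []})

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid("Maxent", {"n_trees": [10]})

    def test_combo_at_enumerates_all(self):
        combos = {c.key() for c in SMALL_GRID.all_combos()}
        assert len(combos) == 6


class TestGridSearch:
    def test_evaluates_each_once(self, tuning_setup):
        table, fold = tuning_setup
        result = grid_search(table, fold, SMALL_GRID, "auc")
        assert result.trainings_performed == 6
        assert len(result.evaluated) == 6

    def test_single_combination(self, tuning_setup):
        table, fold = tuning_setup
        grid = HyperGrid("Maxent", {"reg": [1.0]})
        result = grid_search(table, fold, grid, "auc")
        assert len(result.evaluated) == 1
        assert result.best.combo["reg"] == 1.0


class TestRandomSearch:
    def test_distinct_and_deterministic(self, tuning_setup):
        table, fold = tuning_setup
        grid = HyperGrid("Maxent", {"fc": ["l", "lq"], "reg": [0.3, 1.0, 3.0, 9.0]})
        a = random_search(table, fold, grid, "auc", population_size=5, seed=3)
        b = random_search(table, fold, grid, "auc", population_size=5, seed=3)
        keys_a = {e.combo.key() for e in a.evaluated}
        assert len(keys_a) == 5
        assert keys_a == {e.combo.key() for e in b.evaluated}

    def test_exhaustion_equals_grid(self, tuning_setup):
        table, fold = tuning_setup
        rs = random_search(table, fold, SMALL_GRID, "auc", population_size=99, seed=0)
        gs = grid_search(table, fold, SMALL_GRID, "auc")
        assert {e.combo.key() for e in rs.evaluated} == {
            e.combo.key() for e in gs.evaluated
        }


class TestRankFitness:
    def _ev(self, train, val, order=0):
        return Evaluated(HyperCombo("RF", {}, 0), train, val, order)

    def test_underfit_ranked_last(self):
        a = self._ev(0.9, 0.8, 0)
        b = self._ev(0.7, 0.75, 1)  # validation > train: underfit
        assert rank_fitness([b, a], "auc") == [a, b]

    def test_all_underfit_ordered_by_validation(self):
        a = self._ev(0.5, 0.9, 0)
        b = self._ev(0.5, 0.7, 1)
        assert rank_fitness([b, a], "auc") == [a, b]

    def test_tie_on_validation_breaks_by_train(self):
        a = self._ev(0.9, 0.8, 0)
        b = self._ev(0.85, 0.8, 1)
        assert rank_fitness([b, a], "auc") == [a, b]

    def test_aicc_ascending(self):
        a = self._ev(210.0, None, 0)
        b = self._ev(190.0, None, 1)
        assert rank_fitness([a, b], "aicc") == [b, a]


class TestCrossover:
    GRID = HyperGrid("BRT", {"n_trees": [10, 20, 30], "shrinkage": [0.1, 0.2]})

    def test_identical_parents_no_mutation(self):
        p = HyperCombo("BRT", {"n_trees": 20, "shrinkage": 0.1}, 0)
        child = crossover(p, p, self.GRID, mutation_chance=0.0, rng=0)
        assert child.key() == p.key()

    def test_mutation_skipped_when_no_third_value(self):
        # shrinkage domain has 2 values, both covered by the parents;
        # n_trees mutation picks the value outside the parents
        p1 = HyperCombo("BRT", {"n_trees": 10, "shrinkage": 0.1}, 0)
        p2 = HyperCombo("BRT", {"n_trees": 20, "shrinkage": 0.2}, 0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            child = crossover(p1, p2, self.GRID, mutation_chance=1.0, rng=rng)
            assert child["shrinkage"] in (0.1, 0.2)
            assert child["n_trees"] in (10, 20, 30)

    def test_uniform_inheritance(self):
        p1 = HyperCombo("BRT", {"n_trees": 10, "shrinkage": 0.1}, 0)
        p2 = HyperCombo("BRT", {"n_trees": 20, "shrinkage": 0.2}, 0)
        rng = np.random.default_rng(42)
        hits = np.zeros(2)
        n = 10_000
        for _ in range(n):
            child = crossover(p1, p2, self.GRID, mutation_chance=0.0, rng=rng)
            hits += [child["n_trees"] == 10, child["shrinkage"] == 0.1]
        assert np.all(np.abs(hits / n - 0.5) < 0.02)

    def test_different_methods_rejected(self):
        p1 = HyperCombo("BRT", {}, 0)
        p2 = HyperCombo("RF", {}, 0)
        with pytest.raises(ValueError):
            crossover(p1, p2, self.GRID, 0.0, rng=0)


class TestGeneticAlgorithm:
    def test_training_count_closed_form(self, tuning_setup):
        table, fold = tuning_setup
        grid = HyperGrid(
            "Maxent", {"fc": ["l", "lq"], "reg": [0.3, 0.6, 1.0, 2.0, 4.0, 8.0]}
        )
        ga = GAConfig(population_size=10, generations=3, keep_best=0.4,
                      keep_random=0.2, seed=1)
        result = optimize_model(table, fold, grid, "auc", ga=ga)
        assert expected_trainings(ga) == 10 + 3 * (10 - 4 - 2)
        assert result.trainings_performed == 22

    def test_zero_generations_is_random_search(self, tuning_setup):
        table, fold = tuning_setup
        ga = GAConfig(population_size=4, generations=0, seed=7)
        a = optimize_model(table, fold, SMALL_GRID, "auc", ga=ga)
        b = random_search(table, fold, SMALL_GRID, "auc", population_size=4, seed=7)
        assert [e.combo.key() for e in a.evaluated] == [
            e.combo.key() for e in b.evaluated
        ]

    def test_elitism_best_never_degrades(self, tuning_setup):
        table, fold = tuning_setup
        grid = HyperGrid(
            "Maxent", {"fc": ["l", "lq"], "reg": [0.3, 0.6, 1.0, 2.0, 4.0, 8.0]}
        )
        ga = GAConfig(population_size=6, generations=4, seed=2)
        result = optimize_model(table, fold, grid, "auc", ga=ga)
        best = [g["best"] for g in result.generations_log]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_cache_prevents_retraining(self, tuning_setup):
        table, fold = tuning_setup
        ga = GAConfig(population_size=5, generations=4, seed=3)
        result = optimize_model(table, fold, SMALL_GRID, "auc", ga=ga)
        distinct = len({e.combo.key() for e in result.evaluated})
        actual_fits = result.trainings_performed - result.cache_hits
        assert actual_fits <= SMALL_GRID.n_combinations
        assert distinct <= SMALL_GRID.n_combinations

    def test_keep_fractions_validated(self):
        with pytest.raises(ValueError):
            GAConfig(keep_best=0.8, keep_random=0.4)
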