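"""Pareto filtering, exhaustive enumeration and NSGA-II equivalence."""

import numpy as np
import pytest

from anisann import (
    DesignSpec,
    GAConfig,
    best_condition_per_output,
    enumerate_candidates,
    ga_optimize,
    pareto_filter,
)
from anisann.design import RESPONSE_NAMES
from conftest import make_random_model


def pareto_brute_force(points):
    """O(n²) double-loop nondominated check, independent of the implementation."""
    P = np.asarray(points, dtype=float)
    keep = []
    for i in range(len(P)):
        dominated = False
        for j in range(len(P)):
            if j == i:
                continue
            if np.all(P[j] >= P[i]) and np.any(P[j] > P[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


class TestParetoFilter:
    def test_simple_domination(self):
        assert pareto_filter([(1, 1), (2, 2)]) == [1]

    def test_mutually_nondominated_triple(self):
        assert pareto_filter([(1, 1), (2, 0), (0, 2)]) == [0, 1, 2]

    def test_duplicates_of_kept_point_all_kept(self):
        assert pareto_filter([(2, 2), (1, 1), (2, 2)]) == [0, 2]

    def test_empty_input(self):
        assert pareto_filter([]) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 1, (200, 5))
        assert pareto_filter(P) == pareto_brute_force(P)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(9)
        P = rng.uniform(0, 1, (50, 3))
        perm = rng.permutation(50)
        front_a = {tuple(P[i]) for i in pareto_filter(P)}
        front_b = {tuple(P[perm][i]) for i in pareto_filter(P[perm])}
        assert front_a == front_b


class TestEnumeration:
    def test_default_design_yields_36_candidates(self, design, random_model):
        cands = enumerate_candidates(design, random_model)
        assert len(cands) == 36
        assert len({c.levels for c in cands}) == 36

    def test_reduced_design_yields_30(self):
        design = DesignSpec(fertilizations=("control", "Slavol", "BactoFil",
                                            "Royal Ofert", "vermicompost"))
        model = make_random_model(design, seed=31)
        assert len(enumerate_candidates(design, model)) == 30

    def test_predictions_are_definitional(self, design, random_model):
        for c in enumerate_candidates(design, random_model)[:5]:
            expected = random_model.predict(c.encoded[None, :])[0]
            assert np.allclose(c.predicted, expected)


def exact_front_levels(design, model):
    cands = enumerate_candidates(design, model)
    objs = np.vstack([c.predicted for c in cands])
    return {cands[i].levels for i in pareto_filter(objs)}


class TestGeneticAlgorithm:
    def test_discrete_front_equals_exhaustive_oracle(self, design):
        model = make_random_model(design, seed=21)
        cfg = GAConfig(population_size=100, generations=40, stall_generations=40)
        result = ga_optimize(model, design, cfg, seed=1)
        assert {c.levels for c in result.front} == exact_front_levels(design, model)

    def test_single_global_optimum_collapses_front(self, design):
        model = make_random_model(design, seed=2)
        # unique dominant candidate: every output is the same weighted input sum
        # with distinct level weights, maximal at (year_2, Mošorin, NPK)
        c = np.array([1.0, 0.1, 0.2, 0.3, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        model.params.W1 = np.eye(10)
        model.params.B1 = np.zeros(10)
        model.params.W2 = np.tile(c[:, None], (1, 30))
        model.params.B2 = np.zeros(30)
        model.params.hidden_activation = "identity"
        model.params.output_activation = "identity"
        result = ga_optimize(model, design, GAConfig(population_size=40,
                                                     generations=30), seed=3)
        assert len(result.front) == 1

    def test_same_seed_identical_fronts(self, design, random_model):
        cfg = GAConfig(population_size=20, generations=15)
        r1 = ga_optimize(random_model, design, cfg, seed=7)
        r2 = ga_optimize(random_model, design, cfg, seed=7)
        assert [c.levels for c in r1.front] == [c.levels for c in r2.front]

    def test_zero_generations_returns_initial_front(self, design, random_model):
        cfg = GAConfig(population_size=50, generations=0)
        result = ga_optimize(random_model, design, cfg, seed=5)
        assert result.generations_run == 0
        objs = np.vstack([c.predicted for c in result.front])
        assert pareto_filter(objs) == list(range(len(objs)))

    def test_relaxed_mode_bounds_and_internal_nondomination(self, design, random_model):
        cfg = GAConfig(population_size=30, generations=20, mode="relaxed")
        result = ga_optimize(random_model, design, cfg, seed=11)
        for c in result.front:
            assert c.year is None
            assert np.all(c.encoded >= 0.0) and np.all(c.encoded <= 1.0)
        objs = np.vstack([c.predicted for c in result.front])
        assert pareto_filter(objs) == list(range(len(objs)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=3)
        with pytest.raises(ValueError):
            GAConfig(population_size=11)
        with pytest.raises(ValueError):
            GAConfig(mode="annealed")


class TestBestConditionPerOutput:
    def test_single_candidate_wins_everything(self, design, random_model):
        cfg = GAConfig(population_size=20, generations=5)
        result = ga_optimize(random_model, design, cfg, seed=13)
        solo = type(result)(front=result.front[:1], generations_run=1,
                            population_size=20, mode="discrete")
        winners = best_condition_per_output(solo, list(RESPONSE_NAMES))
        assert all(c is solo.front[0] for c, _ in winners.values())

    def test_interleaved_wins_split_and_values_match(self, design, random_model):
        result = ga_optimize(random_model, design,
                             GAConfig(population_size=40, generations=30), seed=17)
        winners = best_condition_per_output(result, list(RESPONSE_NAMES))
        for j, name in enumerate(RESPONSE_NAMES):
            cand, value = winners[name]
            assert value == pytest.approx(max(c.predicted[j] for c in result.front))
            assert value == pytest.approx(cand.predicted[j])

    def test_empty_front_rejected(self, design, random_model):
        result = ga_optimize(random_model, design,
                             GAConfig(population_size=20, generations=1), seed=19)
        result.front = []
        with pytest.raises(ValueError):
            best_condition_per_output(result, list(RESPONSE_NAMES))
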