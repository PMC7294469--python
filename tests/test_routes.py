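import itertools

import numpy as np
import pytest

from foragesim import (
    GAConfig,
    brute_force_route,
    count_sequences,
    foraging_efficiency,
    ga_route,
    nearest_neighbor_route,
    nn_vs_optimal_gap,
    path_length,
)
from foragesim.studies import random_instance


def enumerate_optimal(start, pts):
    """Independent oracle: plain-Python enumeration of all permutations."""
    best = None
    for perm in itertools.permutations(range(len(pts))):
        ln = path_length(start, pts, perm)
        if best is None or ln < best[1] - 1e-12:
            best = (perm, ln)
    return best


class TestBruteForce:
    def test_single_pellet(self):
        res = brute_force_route((0.0, 0.0), np.array([[3.0, 4.0]]))
        assert res.order == (0,)
        assert res.length_cm == pytest.approx(5.0)

    def test_three_pellet_l_shape(self):
        pts = np.array([[0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
        res = brute_force_route((0.0, 0.0), pts)
        assert res.order == (0, 1, 2)
        assert res.length_cm == pytest.approx(30.0)

    def test_collinear_visits_in_order(self):
        pts = np.array([[30.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        res = brute_force_route((0.0, 0.0), pts)
        assert res.order == (1, 2, 0)

    def test_matches_plain_enumeration(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 100, size=(6, 2))
            res = brute_force_route((0.0, 50.0), pts)
            perm, ln = enumerate_optimal((0.0, 50.0), pts)
            assert res.length_cm == pytest.approx(ln)
            assert res.order == perm

    def test_guard_on_large_instances(self, rng):
        with pytest.raises(ValueError):
            brute_force_route((0.0, 0.0), rng.uniform(0, 100, size=(11, 2)))


class TestGeneticAlgorithm:
    def test_matches_oracle_on_small_instances(self, rng):
        for i in range(5):
            pts = rng.uniform(0, 200, size=(3, 2))
            ga = ga_route((0.0, 50.0), pts, GAConfig(seed=i, n_generations=60))
            bf = brute_force_route((0.0, 50.0), pts)
            assert ga.length_cm == pytest.approx(bf.length_cm)

    def test_deterministic_given_seed(self, rng):
        pts = rng.uniform(0, 200, size=(7, 2))
        a = ga_route((0.0, 50.0), pts, GAConfig(seed=3))
        b = ga_route((0.0, 50.0), pts, GAConfig(seed=3))
        assert a == b

    def test_never_worse_than_initial_population_best(self, rng):
        # with zero generations of improvement budget the GA still reports
        # the best random member; more generations can only improve it
        pts = rng.uniform(0, 200, size=(7, 2))
        short = ga_route((0.0, 50.0), pts, GAConfig(seed=5, n_generations=1))
        long = ga_route((0.0, 50.0), pts, GAConfig(seed=5, n_generations=500))
        assert long.length_cm <= short.length_cm + 1e-9

    def test_more_generations_never_longer(self, rng):
        pts = rng.uniform(0, 200, size=(8, 2))
        lengths = [
            ga_route((0.0, 50.0), pts, GAConfig(seed=9, n_generations=g)).length_cm
            for g in (5, 50, 500)
        ]
        assert lengths == sorted(lengths, reverse=True) or np.all(
            np.diff(lengths) <= 1e-9
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=2)
        with pytest.raises(ValueError):
            GAConfig(n_generations=0)


class TestNearestNeighbor:
    def test_visits_nearer_of_two_first(self):
        pts = np.array([[50.0, 0.0], [10.0, 0.0]])
        assert nearest_neighbor_route((0.0, 0.0), pts).order == (1, 0)

    def test_equidistant_tie_takes_lowest_index(self):
        pts = np.array([[10.0, 10.0], [10.0, -10.0], [30.0, 0.0]])
        assert nearest_neighbor_route((0.0, 0.0), pts).order[0] == 0

    def test_never_shorter_than_oracle(self, arena, rng):
        for _ in range(20):
            inst = random_instance(rng, arena, 7)
            nn = nearest_neighbor_route(arena.start, inst)
            bf = brute_force_route(arena.start, inst)
            assert nn.length_cm >= bf.length_cm - 1e-9


class TestEfficiencyMetrics:
    def test_foraging_efficiency_values(self):
        assert foraging_efficiency(100.0, 100.0) == pytest.approx(1.0)
        assert foraging_efficiency(100.0, 200.0) == pytest.approx(0.5)

    def test_foraging_efficiency_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            foraging_efficiency(0.0, 10.0)
        with pytest.raises(ValueError):
            foraging_efficiency(10.0, -1.0)

    def test_nn_efficiency_in_unit_interval(self, arena, rng):
        for _ in range(10):
            inst = random_instance(rng, arena, 6)
            fe = foraging_efficiency(
                brute_force_route(arena.start, inst).length_cm,
                nearest_neighbor_route(arena.start, inst).length_cm,
            )
            assert 0.0 < fe <= 1.0 + 1e-12

    def test_count_sequences(self):
        assert count_sequences(7) == 5040
        assert count_sequences(0) == 1
        assert count_sequences(3) == 6
        with pytest.raises(ValueError):
            count_sequences(-1)

    def test_gap_zero_when_nn_optimal(self):
        pts = np.array([[10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
        assert nn_vs_optimal_gap((0.0, 0.0), pts) == pytest.approx(0.0)

    def test_gap_invariant_under_rigid_translation(self, arena, rng):
        inst = random_instance(rng, arena, 6)
        g0 = nn_vs_optimal_gap((0.0, 50.0), inst.points)
        shift = np.array([13.0, -7.0])
        g1 = nn_vs_optimal_gap((0.0, 50.0) + shift, inst.points + shift)
        assert g0 == pytest.approx(g1)
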