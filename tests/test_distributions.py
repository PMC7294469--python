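import numpy as np
import pytest

from foragesim import (
    Arena,
    PelletDistribution,
    ScalarField,
    across_trial_min_distance,
    constrain_optimal_length,
    generate_sequence,
    make_cluster_trial,
    optimal_route,
    re_trajectory,
    relative_entropy,
    smooth_density,
)
from foragesim.distributions import DENSITY_FLOOR


class TestClusterTrial:
    def test_three_clusters_of_two_to_three_pellets(self, arena):
        for seed in range(10):
            trial = make_cluster_trial(arena, seed)
            assert 6 <= trial.n_pellets <= 9
            trial.validate(arena)

    def test_zero_variance_single_pellet_at_center(self, arena):
        trial = make_cluster_trial(
            arena, 3, n_clusters=1, pellets_per_cluster_range=(1, 1), cluster_sd_cm=0.0
        )
        assert trial.n_pellets == 1
        # with sd=0 the pellet falls exactly on the (uniform) cluster center
        x, y = trial.points[0]
        assert 20.0 <= x <= arena.length_cm - 20.0
        assert 20.0 <= y <= arena.width_cm - 20.0

    def test_same_seed_reproduces_points(self, arena):
        a = make_cluster_trial(arena, 11)
        b = make_cluster_trial(arena, 11)
        assert np.array_equal(a.points, b.points)

    def test_infeasible_margin_raises(self, arena):
        with pytest.raises(ValueError):
            make_cluster_trial(arena, 0, margin_cm=60.0)

    def test_mean7_preset_places_exactly_seven(self, arena):
        trial = make_cluster_trial(arena, 5, preset="paper_mean7")
        assert trial.n_pellets == 7


class TestGenerateSequence:
    def test_high_repeats_identically(self, high_seq):
        base = high_seq.trials[0].points
        assert all(np.array_equal(t.points, base) for t in high_seq.trials)

    def test_high_across_trial_distance_zero(self, high_seq):
        for prev, cur in zip(high_seq.trials[:-1], high_seq.trials[1:]):
            assert np.all(across_trial_min_distance(cur, prev) == 0.0)

    def test_low_respects_min_shift(self, low_seq):
        for prev, cur in zip(low_seq.trials[:-1], low_seq.trials[1:]):
            assert np.all(across_trial_min_distance(cur, prev) >= 20.0)

    def test_levels_ordered_by_shift_metric(self):
        means = {}
        for level in ("high", "medium", "low"):
            seq = generate_sequence(level, n_sessions=4, seed=21)
            shifts = [
                np.mean(across_trial_min_distance(cur, prev))
                for prev, cur in zip(seq.trials[:-1], seq.trials[1:])
            ]
            means[level] = np.mean(shifts)
        assert means["high"] < means["medium"] < means["low"]

    def test_matched_optimal_lengths_across_levels(self):
        # all accepted placements pass the shared optimal-length constraint
        level_means = []
        for level, seed in (("high", 31), ("medium", 32), ("low", 33)):
            seq = generate_sequence(level, n_sessions=2, seed=seed)
            lens = [
                optimal_route(seq.arena.start, t).length_cm for t in seq.trials[:3]
            ]
            assert np.all(np.abs(np.array(lens) - 250.0) <= 0.15 * 250.0)
            level_means.append(np.mean(lens))
        assert np.ptp(level_means) <= 2 * 0.15 * 250.0

    def test_deterministic_given_seed(self):
        a = generate_sequence("medium", n_sessions=2, seed=5, resample_scatter=True)
        b = generate_sequence("medium", n_sessions=2, seed=5, resample_scatter=True)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.points, tb.points)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            generate_sequence("extreme")


class TestAcrossTrialMinDistance:
    def test_identity_gives_zeros(self):
        d = PelletDistribution(1, [[10.0, 10.0], [30.0, 40.0]])
        assert np.all(across_trial_min_distance(d, d) == 0.0)

    def test_hand_computed_euclidean_minimum(self):
        cur = PelletDistribution(2, [[0.0, 0.0]])
        prev = PelletDistribution(1, [[3.0, 4.0], [10.0, 10.0]])
        assert across_trial_min_distance(cur, prev) == pytest.approx([5.0])

    def test_exact_match_dominates(self):
        cur = PelletDistribution(2, [[50.0, 50.0]])
        prev = PelletDistribution(1, [[50.0, 50.0], [200.0, 10.0], [9.0, 90.0]])
        assert across_trial_min_distance(cur, prev) == pytest.approx([0.0])


class TestSmoothDensity:
    def test_normalized_and_positive(self, arena, rng):
        trial = make_cluster_trial(arena, 2)
        field = smooth_density(trial, arena)
        assert field.sum() == pytest.approx(1.0)
        assert np.all(field.values > 0)

    def test_single_pellet_mass_in_one_cell(self, arena):
        field = smooth_density(PelletDistribution(1, [[100.0, 50.0]]), arena)
        # all but the floor mass sits in the pellet's cell
        assert field.max() > 1.0 - arena.n_cells * DENSITY_FLOOR * 2
        r, c = arena.point_to_cell(100.0, 50.0)
        assert field.values[r, c] == field.max()

    def test_deterministic(self, arena):
        t = make_cluster_trial(arena, 4)
        a = smooth_density(t, arena)
        b = smooth_density(PelletDistribution(1, t.points.copy()), arena)
        assert np.array_equal(a.values, b.values)

    def test_empty_input_rejected(self, arena):
        with pytest.raises(ValueError):
            smooth_density([], arena)


class TestRelativeEntropy:
    def test_identity_is_zero(self, arena):
        P = smooth_density(make_cluster_trial(arena, 6), arena)
        assert relative_entropy(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_two_cell_uniform_is_one_bit(self):
        small = Arena(length_cm=4.0, width_cm=4.0, n_cols=2, n_rows=2)
        eps = 1e-9
        p = np.array([[1.0 - 2 * eps, eps], [eps, 0.0]])
        p[0, 0] = 1.0 - p.ravel()[1:].sum()
        q = np.array([[0.5 - eps, 0.5 - eps], [eps, eps]])
        val = relative_entropy(
            ScalarField(p, small), ScalarField(q, small)
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative_for_generated_pairs(self, arena):
        for seed in range(5):
            P = smooth_density(make_cluster_trial(arena, seed), arena)
            Q = smooth_density(make_cluster_trial(arena, seed + 100), arena)
            assert relative_entropy(P, Q) >= 0.0

    def test_mismatched_grids_rejected(self, arena):
        other = Arena(n_cols=10, n_rows=10)
        P = smooth_density(make_cluster_trial(arena, 1), arena)
        Q = ScalarField(np.full((10, 10), 1.0 / 100.0), other)
        with pytest.raises(ValueError):
            relative_entropy(P, Q)

    def test_unnormalized_rejected(self, arena):
        P = smooth_density(make_cluster_trial(arena, 1), arena)
        bad = ScalarField(P.values * 2.0, arena)
        with pytest.raises(ValueError):
            relative_entropy(P, bad)


class TestReTrajectory:
    def test_identical_trials_give_zero(self, high_seq):
        re = re_trajectory(high_seq)
        assert re == pytest.approx(np.zeros(high_seq.n_trials - 1), abs=1e-9)

    def test_randomized_shows_no_decrease(self, low_seq):
        re = re_trajectory(low_seq)
        slope = np.polyfit(np.arange(len(re)), re, 1)[0]
        # no systematic decay of surprise for actively randomized placements
        assert slope > -0.1

    def test_requires_two_trials(self, arena):
        seq = generate_sequence("high", n_sessions=1, trials_per_session=1, seed=1)
        with pytest.raises(ValueError):
            re_trajectory(seq)


class TestOptimalLengthConstraint:
    def test_exact_target_accepted(self, arena):
        trial = make_cluster_trial(arena, 13)
        lo = optimal_route(arena.start, trial).length_cm
        assert constrain_optimal_length(trial, lo, 0.0, start=arena.start)

    def test_zero_tolerance_rejects_perturbation(self, arena):
        trial = make_cluster_trial(arena, 13)
        lo = optimal_route(arena.start, trial).length_cm
        assert not constrain_optimal_length(trial, lo + 1.0, 0.0, start=arena.start)
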