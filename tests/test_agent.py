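import numpy as np
import pytest

from foragesim import (
    AgentParams,
    AgentState,
    Arena,
    PelletDistribution,
    ScalarField,
    combine_maps,
    distance_field,
    memory_map,
    nearest_neighbor_route,
    prior_expectation,
    run_trial,
    sensory_map,
    step_agent,
)
from foragesim.agent import occupancy_map
from foragesim.studies import random_grid_instance


class TestAgentParams:
    @pytest.mark.parametrize(
        "kwargs", [{"sw": -0.1, "se": 1.0}, {"sw": 1.1, "se": 1.0}, {"sw": 0.5, "se": -1.0}, {"sw": 0.5, "se": 1.0, "md": 0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AgentParams(**kwargs)


class TestPriorExpectation:
    def test_repeated_history_gives_indicator(self, high_seq):
        pe = prior_expectation(high_seq, t=6, md=None)
        occ = occupancy_map(high_seq.trials[0], high_seq.arena)
        assert np.array_equal(pe.values, occ)

    def test_md1_equals_previous_trial_occupancy(self, medium_seq):
        t = 8
        pe = prior_expectation(medium_seq, t=t, md=1)
        occ = occupancy_map(medium_seq.trials[t - 2], medium_seq.arena)
        assert np.array_equal(pe.values, occ)

    def test_deep_memory_averages_first_ten_trials(self, medium_seq):
        pe = prior_expectation(medium_seq, t=11, md=10)
        expected = np.mean(
            [occupancy_map(tr, medium_seq.arena) for tr in medium_seq.trials[:10]],
            axis=0,
        )
        assert np.allclose(pe.values, expected)

    def test_no_prior_before_trial_two(self, medium_seq):
        with pytest.raises(ValueError):
            prior_expectation(medium_seq, t=1, md=1)


class TestMaps:
    def test_distance_zero_at_own_cell_center(self, arena):
        x, y = arena.cell_center(10, 20)
        d = distance_field((x, y), arena)
        assert d.values[10, 20] == 0.0

    def test_distance_symmetry(self, arena):
        x, y = arena.cell_center(20, 40)
        d = distance_field((x, y), arena)
        assert d.values[20, 30] == pytest.approx(d.values[20, 50])

    def test_distance_max_at_a_corner(self, arena):
        d = distance_field((30.0, 20.0), arena)
        corner_vals = [d.values[r, c] for r in (0, 39) for c in (0, 79)]
        assert d.max() == pytest.approx(max(corner_vals))

    def test_memory_map_limits(self, arena, rng):
        pe = ScalarField(rng.uniform(0, 1, arena.shape), arena)
        r, c = 20, 32
        pos = arena.cell_center(r, c)
        d = distance_field(pos, arena)
        m = memory_map(pe, d)
        # full credit at the agent's own cell (distance 0), none at the farthest
        assert m.values[r, c] == pytest.approx(pe.values[r, c])
        far = np.unravel_index(np.argmax(d.values), d.values.shape)
        assert m.values[far] == 0.0
        assert np.all(m.values <= pe.values + 1e-12)

    def test_sensory_map_se_zero_is_cr(self, arena):
        cr = ScalarField(np.zeros(arena.shape), arena)
        cr.values[5, 5] = 1.0
        cr.values[30, 70] = 1.0
        d = distance_field((10.0, 10.0), arena)
        s = sensory_map(cr, d, se=0.0)
        assert np.array_equal(s.values, cr.values)

    def test_sensory_map_decays_with_distance(self, arena):
        cr = ScalarField(np.zeros(arena.shape), arena)
        cr.values[20, 10] = 1.0  # near
        cr.values[20, 70] = 1.0  # far
        d = distance_field((0.0, 50.0), arena)
        for se in (0.5, 2.0, 8.0):
            s = sensory_map(cr, d, se=se)
            assert s.values[20, 10] > s.values[20, 70]

    def test_combine_maps_convexity(self, arena, rng):
        s = ScalarField(rng.uniform(0, 1, arena.shape), arena)
        m = ScalarField(rng.uniform(0, 1, arena.shape), arena)
        assert np.array_equal(combine_maps(s, m, 1.0).values, s.values)
        assert np.array_equal(combine_maps(s, m, 0.0).values, m.values)
        assert np.allclose(combine_maps(s, s, 0.5).values, s.values)


class TestStepAgent:
    def make_state(self, arena, points):
        return AgentState.initial(PelletDistribution(1, points), arena)

    def test_moves_toward_single_positive_cell_and_collects(self, arena):
        x, y = arena.cell_center(20, 10)
        state = self.make_state(arena, [[x, y]])
        p = ScalarField(np.zeros(arena.shape), arena)
        p.values[20, 10] = 1.0
        for _ in range(50):
            step_agent(state, p, arena.cell_diag, arena)
            if not state.remaining.any():
                break
        assert state.acquired == [0]
        assert state.path_length_cm == pytest.approx(np.hypot(x - 0.0, y - 50.0))

    def test_at_argmax_position_unchanged_detection_applied(self, arena):
        state = self.make_state(arena, [[200.0, 80.0]])
        r, c = arena.point_to_cell(*state.position)
        x, y = arena.cell_center(r, c)
        state.position = np.array([x, y])
        p = ScalarField(np.zeros(arena.shape), arena)
        p.values[r, c] = 1.0
        step_agent(state, p, arena.cell_diag, arena)
        assert np.array_equal(state.position, [x, y])
        assert state.visited_empty[r, c]

    def test_equal_maxima_resolve_to_nearer_cell(self, arena):
        state = self.make_state(arena, [[200.0, 80.0]])
        p = ScalarField(np.zeros(arena.shape), arena)
        p.values[20, 5] = 1.0   # near the start
        p.values[20, 60] = 1.0  # far
        step_agent(state, p, arena.cell_diag, arena)
        tx, _ = arena.cell_center(20, 5)
        assert state.position[0] < 10.0  # moved toward the near maximum

    def test_all_zero_map_raises(self, arena):
        state = self.make_state(arena, [[200.0, 80.0]])
        with pytest.raises(ValueError):
            step_agent(state, ScalarField(np.zeros(arena.shape), arena), 4.0, arena)


def naive_run(trial, history, params, arena, max_steps=5000):
    """Independent reimplementation of the trial loop from the public map
    operations and step_agent (full-grid evaluation, no candidate pruning)."""
    state = AgentState.initial(trial, arena)
    if trial.trial_index >= 2:
        pe = prior_expectation(history, trial.trial_index, params.md)
    else:
        pe = ScalarField(np.zeros(arena.shape), arena)
    for _ in range(max_steps):
        if not state.remaining.any():
            break
        d = distance_field(state.position, arena)
        m = memory_map(pe, d)
        cr = ScalarField(np.zeros(arena.shape), arena)
        pts = state.pellets[state.remaining]
        cr.values.ravel()[arena.points_to_flat_cells(pts)] = 1.0
        s = sensory_map(cr, d, params.se)
        p = combine_maps(s, m, params.sw)
        p.values[state.visited_empty] = 0.0
        if p.max() <= 0:
            break
        step_agent(state, p, arena.cell_diag, arena)
    return state


class TestRunTrial:
    def test_sensory_limit_reproduces_nearest_neighbor(self, arena, rng):
        for _ in range(10):
            inst = random_grid_instance(rng, arena, 7)
            res = run_trial(inst, None, AgentParams(sw=1.0, se=0.0), arena)
            nn = nearest_neighbor_route(arena.start, inst)
            assert res.completed
            assert res.acquisition.order == nn.order

    def test_memory_only_on_repeated_history_collects_all(self, high_seq):
        res = run_trial(
            high_seq.trials[5],
            high_seq,
            AgentParams(sw=0.0, se=0.0, md=None),
            high_seq.arena,
        )
        assert res.completed
        assert len(res.acquisition.order) == high_seq.trials[5].n_pellets

    def test_memory_only_displaced_resorts_to_long_sweep(self, low_seq):
        # stale priors force the fallback sweep: the trial still completes
        # but at a path length far beyond the optimal route
        res = run_trial(
            low_seq.trials[5], low_seq, AgentParams(sw=0.0, se=0.0, md=1), low_seq.arena
        )
        assert res.completed
        assert res.path_length_cm > 4 * res.acquisition.length_cm

    def test_bit_reproducible(self, medium_seq):
        params = AgentParams(sw=0.5, se=4.0, md=2)
        a = run_trial(medium_seq.trials[7], medium_seq, params, medium_seq.arena)
        b = run_trial(medium_seq.trials[7], medium_seq, params, medium_seq.arena)
        assert a.path_length_cm == b.path_length_cm
        assert a.acquisition.order == b.acquisition.order
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_matches_naive_public_api_loop(self, medium_seq):
        """The pruned trial loop must replicate a full-grid composition of
        the public map operations step by step."""
        arena = medium_seq.arena
        for t, params in [
            (5, AgentParams(sw=0.6, se=4.0, md=2)),
            (9, AgentParams(sw=0.3, se=8.0, md=None)),
            (9, AgentParams(sw=1.0, se=2.0, md=1)),
        ]:
            trial = medium_seq.trials[t - 1]
            fast = run_trial(trial, medium_seq, params, arena)
            slow = naive_run(trial, medium_seq, params, arena)
            assert fast.acquisition.order == tuple(slow.acquired)
            assert fast.path_length_cm == pytest.approx(slow.path_length_cm)

    def test_collected_pellets_never_reappear(self, medium_seq):
        res = run_trial(
            medium_seq.trials[6],
            medium_seq,
            AgentParams(sw=0.7, se=8.0, md=1),
            medium_seq.arena,
        )
        assert len(set(res.acquisition.order)) == len(res.acquisition.order)

    def test_history_required_after_first_trial(self, medium_seq):
        with pytest.raises(ValueError):
            run_trial(
                medium_seq.trials[3], None, AgentParams(sw=0.5, se=1.0), medium_seq.arena
            )

    def test_cumulative_memory_no_worse_than_single_on_repeats(self, high_seq):
        # direction of the memory-depth effect on fully repeated sequences
        lengths = {}
        for md in (1, None):
            tot = 0.0
            for t in range(7, 13):
                res = run_trial(
                    high_seq.trials[t - 1],
                    high_seq,
                    AgentParams(sw=0.25, se=8.0, md=md),
                    high_seq.arena,
                    record_path=False,
                )
                tot += res.path_length_cm
            lengths[md] = tot
        assert lengths[None] <= lengths[1] + 1e-9
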