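"""Action-selection rules, value iteration, and the exploration loop."""

import numpy as np
import pytest

from pigexplore import environments as env
from pigexplore import inference as inf
from pigexplore import information as info
from pigexplore import strategies as strat


class TestChooseRandom:
    def test_uniform_frequencies(self, rng):
        draws = np.array([strat.choose_random(4, rng) for _ in range(10_000)])
        freqs = np.bincount(draws, minlength=4) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        np.testing.assert_allclose(freqs, 0.25, atol=3 * se)

    def test_single_action(self, rng):
        assert strat.choose_random(1, rng) == 0


class TestChooseUnembodied:
    def test_symmetric_prior_breaks_ties_uniformly(self, rng):
        model = inf.PosteriorModel.for_dense(5, 2)
        pairs = {strat.choose_unembodied(model, rng) for _ in range(400)}
        assert len(pairs) > 5  # many distinct maximizers visited

    def test_returns_table_maximum(self, rng):
        model = inf.PosteriorModel.for_dense(5, 2)
        for _ in range(15):
            model.record_observation(rng.integers(2), rng.integers(5),
                                     rng.integers(5))
        table = info.utility_table(model, "pig").values
        a, s = strat.choose_unembodied(model, rng)
        assert table[a, s] == table.max()

    def test_heavily_sampled_row_no_longer_chosen(self, rng):
        model = inf.PosteriorModel.for_dense(4, 2)
        for _ in range(60):
            model.record_observation(0, 0, rng.integers(4))
        picks = {strat.choose_unembodied(model, rng) for _ in range(50)}
        assert (0, 0) not in picks


class TestChooseGreedy:
    def test_matches_argmax_when_unique(self, rng):
        model = inf.PosteriorModel.for_dense(4, 3)
        for _ in range(30):
            values = rng.normal(size=(3, 4))
            table = info.UtilityTable(values=values, utility_name="pig")
            s = int(rng.integers(4))
            assert strat.choose_greedy(model, s, table, rng) == \
                np.argmax(values[:, s])

    def test_uniform_tie_break(self, rng):
        model = inf.PosteriorModel.for_dense(2, 3)
        table = info.UtilityTable(values=np.zeros((3, 2)), utility_name="pig")
        draws = np.array([strat.choose_greedy(model, 0, table, rng)
                          for _ in range(3000)])
        freqs = np.bincount(draws, minlength=3) / 3000
        assert np.all(np.abs(freqs - 1 / 3) < 3 * np.sqrt(2 / 9 / 3000))


def vi_oracle(values, theta, gamma, horizon):
    """Exhaustive recursion over the backup definition."""
    m, n = values.shape

    def q(a, s, depth):
        if depth == 0:
            return values[a, s]
        future = sum(theta[a, s, s2] * max(q(a2, s2, depth - 1)
                                           for a2 in range(m))
                     for s2 in range(n) if theta[a, s, s2] > 0)
        return values[a, s] + gamma * future

    return np.array([[q(a, s, horizon) for s in range(n)] for a in range(m)])


class TestValueIterate:
    def test_horizon_zero_returns_utility(self, rng):
        world = env.sample_dense_world(4, 2, rng)
        values = rng.normal(size=(2, 4))
        out = strat.value_iterate(values, world, horizon=0)
        np.testing.assert_array_equal(out.q, values)

    def test_zero_utility_stays_zero(self, rng):
        world = env.sample_dense_world(4, 2, rng)
        out = strat.value_iterate(np.zeros((2, 4)), world, horizon=7)
        np.testing.assert_allclose(out.q, 0.0)

    def test_two_state_deterministic_chain(self):
        """One action leads to state 1 (utility 1), the other stays;
        the 2-step backup matches the exhaustive recursion."""
        theta = np.zeros((2, 2, 2))
        theta[0, 0, 1] = theta[0, 1, 0] = 1.0  # swap action
        theta[1, 0, 0] = theta[1, 1, 1] = 1.0  # stay action
        values = np.array([[0.0, 1.0], [0.0, 1.0]])
        got = strat.value_iterate(values, theta, gamma=0.95, horizon=2).q
        np.testing.assert_allclose(got, vi_oracle(values, theta, 0.95, 2),
                                   atol=1e-12)

    def test_matches_oracle_on_random_worlds(self, rng):
        for _ in range(5):
            world = env.sample_dense_world(3, 2, rng)
            values = rng.uniform(size=(2, 3))
            got = strat.value_iterate(values, world, gamma=0.9, horizon=3).q
            np.testing.assert_allclose(
                got, vi_oracle(values, world.theta, 0.9, 3), atol=1e-10)

    def test_rejects_unnormalized_kernel(self, rng):
        theta = np.full((1, 2, 2), 0.3)
        with pytest.raises(ValueError):
            strat.value_iterate(np.zeros((1, 2)), theta)


class TestHeuristics:
    def test_lta_picks_least_taken(self, rng):
        counts = np.array([[0.0], [5.0], [5.0], [5.0]])
        assert strat.choose_lta(counts, 0, rng) == 0

    def test_lta_pigeonhole_round_robin(self, rng):
        """Over M*k selections in one state every action is taken
        exactly k times."""
        counts = np.zeros((4, 1))
        for _ in range(4 * 6):
            a = strat.choose_lta(counts, 0, rng)
            counts[a, 0] += 1
        np.testing.assert_array_equal(counts[:, 0], 6)

    def test_cb_prefers_unvisited_deterministic_target(self, rng):
        model = inf.PosteriorModel.for_dense(3, 2)
        model.theta_hat[0, 0] = [0.0, 1.0, 0.0]
        model.theta_hat[1, 0] = [0.0, 0.0, 1.0]
        state_counts = np.array([4.0, 3.0, 0.0])
        assert strat.choose_cb(model, state_counts, 0, rng) == 1

    def test_cb_matches_expected_count_minimum(self, rng):
        model = inf.PosteriorModel.for_dense(5, 3)
        for _ in range(40):
            model.record_observation(rng.integers(3), rng.integers(5),
                                     rng.integers(5))
        counts = rng.integers(0, 10, size=5).astype(float)
        expected = model.theta_hat[:, 2, :] @ counts
        assert expected[strat.choose_cb(model, counts, 2, rng)] == \
            pytest.approx(expected.min())


class TestPEIGQ:
    def test_single_update_arithmetic(self):
        agent = strat.PEIGQ(learning_rate=0.1, gamma=0.95, epsilon=0.0)
        model = inf.PosteriorModel.for_dense(2, 1)
        agent.reset(model, env.CMCKernel(np.full((1, 2, 2), 0.5)),
                    np.random.default_rng(0))
        old_row = model.row(0, 0).copy()
        model.record_observation(0, 0, 0)
        agent.observe(0, 0, 0, old_row)
        r = info.kl_divergence([2 / 3, 1 / 3], [0.5, 0.5])
        assert agent.q[0, 0] == pytest.approx(0.1 * r, abs=1e-12)
        assert np.all(agent.q.ravel()[1:] == 0)

    def test_fully_known_world_gives_no_drive(self):
        """With zero surprise forever Q stays 0, so actions stay
        uniform."""
        model = inf.PosteriorModel.for_onetwothree(4)
        world, _ = env.sample_onetwothree_world(4, np.random.default_rng(2))
        # reveal every deterministic a=1 target so its updates are silent
        for s in range(4):
            t = int(np.argmax(world.theta[0, s]))
            model.record_observation(0, s, t)
        agent = strat.PEIGQ()
        agent.reset(model, world, np.random.default_rng(3))
        for s in range(4):
            t = int(np.argmax(world.theta[0, s]))
            old = model.row(0, s).copy()
            model.record_observation(0, s, t)
            agent.observe(0, s, t, old)
        np.testing.assert_array_equal(agent.q, 0.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            strat.PEIGQ(learning_rate=0.0)
        with pytest.raises(ValueError):
            strat.PEIGQ(epsilon=1.5)


class TestRunExploration:
    def test_zero_steps_records_prior(self, rng):
        world = env.sample_dense_world(rng=rng)
        trace = strat.run_exploration(world, "random", 0, seed=0)
        assert trace.n_steps == 0
        model = inf.PosteriorModel.for_dense()
        assert trace.missing_info[0] == pytest.approx(
            info.missing_information(world, model.theta_hat))

    def test_counts_match_steps(self, rng):
        world = env.sample_dense_world(rng=rng)
        model = inf.PosteriorModel.for_dense()
        strat.run_exploration(world, "random", 57, seed=1, model=model)
        assert model.total == 57

    def test_unknown_strategy_rejected(self, rng):
        world = env.sample_dense_world(rng=rng)
        with pytest.raises(ValueError):
            strat.run_exploration(world, "mystery", 5, seed=0)

    def test_vi_horizon_zero_reproduces_greedy(self):
        """PIG(VI) with a zero-step horizon equals greedy PIG
        action-for-action on the same random stream."""
        world = env.sample_dense_world(rng=np.random.default_rng(6))
        t1 = strat.run_exploration(
            world, strat.VIUtility("pig", horizon=0), 120,
            rng=np.random.default_rng(42),
            model=inf.PosteriorModel.for_dense())
        t2 = strat.run_exploration(
            world, "pig-greedy", 120, rng=np.random.default_rng(42),
            model=inf.PosteriorModel.for_dense())
        np.testing.assert_array_equal(t1.actions, t2.actions)
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_vi_plus_coincides_when_model_is_truth(self):
        """Planning with the learned kernel equals planning with the
        true kernel when they agree."""
        model = inf.PosteriorModel.for_dense(6, 3)
        world = env.CMCKernel(model.theta_hat.copy())
        t1 = strat.run_exploration(world, "pig-vi", 80,
                                   rng=np.random.default_rng(5),
                                   model=inf.PosteriorModel.for_dense(6, 3))
        t2 = strat.run_exploration(world, "pig-vi+", 80,
                                   rng=np.random.default_rng(5),
                                   model=inf.PosteriorModel.for_dense(6, 3))
        # identical first action; afterwards the learned kernel drifts
        assert t1.actions[0] == t2.actions[0]

    def test_missing_info_declines_on_average(self, rng):
        world = env.sample_dense_world(rng=np.random.default_rng(10))
        curves = np.stack([
            strat.run_exploration(world, "random", 300, seed=i,
                                  eval_every=50).missing_info
            for i in range(30)
        ])
        mean = curves.mean(axis=0)
        assert mean[-1] < mean[0]
        assert np.all(np.diff(mean) < 0.02 * mean[0])

    def test_snapshots_are_copies(self, rng):
        world = env.sample_dense_world(rng=rng)
        model = inf.PosteriorModel.for_dense()
        trace = strat.run_exploration(world, "random", 20, seed=2,
                                      model=model, snapshot_steps=[10, 20])
        assert set(trace.snapshots) == {10, 20}
        snap = trace.snapshots[20].copy()
        model.record_observation(0, 0, 0)
        np.testing.assert_array_equal(trace.snapshots[20], snap)

    def test_unembodied_teleports_are_recorded(self):
        world, _ = env.sample_onetwothree_world(rng=np.random.default_rng(1))
        trace = strat.run_exploration(world, "unembodied", 40, seed=3,
                                      model=inf.PosteriorModel.for_onetwothree())
        assert trace.n_steps == 40
        assert trace.missing_info[-1] < trace.missing_info[0]

    def test_trace_serialization(self, rng, tmp_path):
        world = env.sample_dense_world(rng=rng)
        trace = strat.run_exploration(world, "random", 25, seed=4)
        df = trace.to_frame()
        assert list(df.columns) == ["step", "state", "action"]
        assert len(df) == 25
        summary = trace.summary()
        assert summary["n_steps"] == 25
        assert len(summary["missing_info"]) == len(summary["eval_times"])
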