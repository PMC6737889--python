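import numpy as np
import pytest

import basalq as bq
from basalq.qlearning import (
    QTable,
    TrainingConfig,
    Transition,
    fit_offline,
    fit_online,
    greedy_policy,
    pessimistic_policy,
    q_update,
    select_action,
    value_iteration,
)


def _mdp_transitions(rewards, next_states, terminal=False):
    """Exhaustive one-sample-per-pair transition set for a deterministic MDP."""
    n_s, n_a = rewards.shape
    return [
        Transition(s, a + 1, float(rewards[s, a]), int(next_states[s, a]), terminal)
        for s in range(n_s)
        for a in range(n_a)
    ]


class TestQUpdate:
    def test_collapses_to_immediate_reward(self):
        q = QTable.zeros(4, 2)
        q_update(q, Transition(0, 1, 1.0, 2), alpha=1.0, gamma=0.0)
        assert q.values[0, 0] == 1.0
        assert q.visit_counts[0, 0] == 1
        assert np.count_nonzero(q.values) == 1

    def test_bootstrap_arithmetic(self):
        q = QTable.zeros(4, 2)
        q.values[0, 0] = 0.5
        q.values[3] = [2.0, 1.0]
        q_update(q, Transition(0, 1, 1.0, 3), alpha=0.1, gamma=0.9)
        assert q.values[0, 0] == pytest.approx(0.73)

    def test_zero_step_size_leaves_q_unchanged(self):
        q = QTable.zeros(4, 2)
        q.values[:] = 0.4
        q_update(q, Transition(1, 2, 5.0, 0), alpha=0.0, gamma=0.9)
        assert np.all(q.values == 0.4)

    def test_terminal_drops_bootstrap(self):
        q = QTable.zeros(4, 2)
        q.values[3] = [100.0, 100.0]
        q_update(q, Transition(0, 1, 1.0, 3, terminal=True), alpha=1.0, gamma=0.9)
        assert q.values[0, 0] == 1.0

    def test_nonfinite_reward_rejected(self):
        with pytest.raises(ValueError):
            Transition(0, 1, float("nan"), 1)

    def test_state_vector_states_accepted(self):
        q = QTable.zeros()
        s = bq.StateVector(2, 4, 1, 1)
        q_update(q, Transition(s, 3, 1.0, s, terminal=True), alpha=1.0, gamma=0.9)
        assert q.values[bq.state_index(s), 2] == 1.0


class TestSelectAction:
    def test_pure_greedy_unique_max(self, rng):
        q = QTable.zeros(1, 6)
        q.values[0] = [0, 1, 0, 0, 0, 0]
        assert select_action(q, 0, epsilon=0.0, rng=rng) == 2

    def test_tie_break_lowest_index(self, rng):
        q = QTable.zeros(1, 6)
        assert select_action(q, 0, epsilon=0.0, rng=rng) == 1

    def test_full_exploration_is_uniform(self):
        rng = np.random.default_rng(123)
        q = QTable.zeros(1, 6)
        draws = np.array([select_action(q, 0, epsilon=1.0, rng=rng) for _ in range(60_000)])
        freqs = np.bincount(draws, minlength=7)[1:] / 60_000
        se = np.sqrt((1 / 6) * (5 / 6) / 60_000)
        assert np.all(np.abs(freqs - 1 / 6) < 3 * se)


class TestFitOffline:
    def test_single_transition(self):
        cfg = TrainingConfig(alpha=1.0, gamma=0.0, n_epochs=1)
        q, report = fit_offline([Transition(5, 2, 2.5, 6, terminal=True)], cfg)
        assert q.values[5, 1] == 2.5
        assert np.count_nonzero(q.values) == 1
        assert report.n_sweeps == 1

    def test_empty_input_rejected(self):
        with pytest.raises(bq.NoDataError):
            fit_offline([], TrainingConfig())

    def test_seed_determinism(self, small_cohort):
        trans = bq.cohort_to_transitions(small_cohort)
        cfg = TrainingConfig(seed=11, n_epochs=5)
        q1, _ = fit_offline(trans, cfg)
        q2, _ = fit_offline(trans, cfg)
        assert np.array_equal(q1.values, q2.values)
        assert np.array_equal(q1.visit_counts, q2.visit_counts)

    @pytest.mark.parametrize("gamma", [0.5, 0.9])
    def test_matches_value_iteration_fixed_point(self, gamma):
        """Replay on a deterministic 4-state 2-action MDP reaches Q*."""
        rng = np.random.default_rng(42)
        rewards = rng.uniform(-1, 1, size=(4, 2))
        next_states = rng.integers(0, 4, size=(4, 2))
        q_star = value_iteration(rewards, next_states, gamma)
        cfg = TrainingConfig(alpha=1.0, gamma=gamma, n_epochs=2000, tolerance=1e-9)
        q, report = fit_offline(
            _mdp_transitions(rewards, next_states), cfg, n_states=4, n_actions=2
        )
        assert report.converged
        assert np.max(np.abs(q.values - q_star)) < 1e-6

    def test_policy_invariant_to_reward_scale(self):
        rng = np.random.default_rng(3)
        rewards = rng.uniform(-1, 1, size=(6, 3))
        next_states = rng.integers(0, 6, size=(6, 3))
        cfg = TrainingConfig(alpha=1.0, gamma=0.9, n_epochs=2000, tolerance=1e-10)
        q1, _ = fit_offline(_mdp_transitions(rewards, next_states), cfg, 6, 3)
        q2, _ = fit_offline(_mdp_transitions(rewards * 7.0, next_states), cfg, 6, 3)
        assert np.array_equal(np.argmax(q1.values, axis=1), np.argmax(q2.values, axis=1))

    def test_visit_schedule_recovers_mean_reward_at_gamma_zero(self):
        """With gamma=0 and 1/n steps, Q(s,a) is the mean observed reward."""
        rng = np.random.default_rng(9)
        rewards = rng.normal(size=40)
        transitions = [Transition(0, 1, float(r), 0, terminal=True) for r in rewards]
        cfg = TrainingConfig(
            gamma=0.0, alpha_schedule="visit_count", n_epochs=1, tolerance=1e-12
        )
        q, _ = fit_offline(transitions, cfg, n_states=1, n_actions=2)
        assert q.values[0, 0] == pytest.approx(rewards.mean())


class _SingleStateSim:
    """One-state environment rewarding only action 3; terminates each step."""

    def __init__(self):
        self.state = bq.StateVector(1, 1, 1, 1)

    def reset(self):
        return self.state

    def step(self, action):
        return self.state, (1.0 if action == 3 else 0.0), True


class TestFitOnline:
    def test_learns_the_rewarding_action(self):
        cfg = TrainingConfig(alpha=0.5, gamma=0.0, epsilon=1.0, seed=5)
        q = fit_online(_SingleStateSim(), cfg, n_episodes=200)
        assert q.best_action(bq.StateVector(1, 1, 1, 1)) == 3

    def test_seed_determinism(self):
        p = bq.SimParams(n_patients=5, visits_per_patient=8, seed=2)
        cfg = TrainingConfig(seed=4, epsilon=0.3)
        q1 = fit_online(bq.CohortSimulator(p, seed=2), cfg, n_episodes=20)
        q2 = fit_online(bq.CohortSimulator(p, seed=2), cfg, n_episodes=20)
        assert np.array_equal(q1.values, q2.values)

    def test_zero_episodes_keeps_initialization(self):
        cfg = TrainingConfig(q_init=0.25)
        q = fit_online(_SingleStateSim(), cfg, n_episodes=0)
        assert np.all(q.values == 0.25)
        assert q.visit_counts.sum() == 0


class TestGreedyPolicy:
    def test_one_hot_rows(self):
        q = QTable.zeros()
        q.values[0, 2] = 5.0
        q.visit_counts[0, 2] = 1
        policy = greedy_policy(q)
        assert policy.loc[0, "action"] == 3
        assert bool(policy.loc[0, "visited"])
        assert bq.interval_of(int(policy.loc[0, "action"])).lower == 20

    def test_unvisited_states_flagged_and_tie_broken(self):
        policy = greedy_policy(QTable.zeros())
        assert (policy["action"] == 1).all()
        assert (~policy["visited"]).all()
        assert len(policy) == 306

    def test_decoded_levels_round_trip(self):
        policy = greedy_policy(QTable.zeros())
        row = policy.loc[120]
        assert (
            row["hba1c_level"], row["bmi_level"], row["activity_level"], row["alcohol_level"]
        ) == (2, 4, 1, 1)


class TestPessimisticPolicy:
    def test_rare_lucky_action_is_demoted(self):
        q = QTable.zeros(1, 3)
        q.values[0] = [0.0, 1.0, 1.2]
        q.visit_counts[0] = [0, 100, 1]
        assert pessimistic_policy(q, sigma=1.0)[0] == 2

    def test_unobserved_actions_cannot_win(self):
        q = QTable.zeros(1, 3)
        q.values[0] = [0.0, -0.5, 0.0]  # action 2 observed, others not
        q.visit_counts[0] = [0, 50, 0]
        assert pessimistic_policy(q, sigma=1.0)[0] == 2

    def test_states_without_data_fall_back_to_first_action(self):
        q = QTable.zeros(2, 3)
        assert pessimistic_policy(q, sigma=1.0)[1] == 1


def test_qtable_save_load_roundtrip(tmp_path, small_cohort):
    trans = bq.cohort_to_transitions(small_cohort)
    q, _ = fit_offline(trans, TrainingConfig(n_epochs=3))
    qpath, cpath = tmp_path / "q.csv", tmp_path / "q_counts.csv"
    q.save(qpath, cpath, header_lines=["seed=0"])
    loaded = QTable.load(qpath, cpath)
    assert np.allclose(loaded.values, q.values)
    assert np.array_equal(loaded.visit_counts, q.visit_counts)
    assert qpath.read_text().startswith("# seed=0")


def test_training_config_validation():
    for kwargs in (
        dict(alpha=0.0), dict(alpha=1.5), dict(gamma=-0.1), dict(epsilon=2.0),
        dict(n_epochs=0), dict(tolerance=0.0), dict(alpha_schedule="bogus"),
    ):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)
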