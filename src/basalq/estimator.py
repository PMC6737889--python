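"""scikit-learn-style estimator wrapping the tabular Q-learner.

`QLearningDoseRecommender` fits on a visit-record table (longitudinal
trajectories) and predicts a dose-interval action for new observations, so
it composes with sklearn pipelines and model selection. It is a thin,
stateful facade over :func:`basalq.qlearning.fit_offline` /
:func:`fit_online`; the tabular primitives remain available as functions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import NoDataError
from .qlearning import (
    ConvergenceReport,
    QTable,
    TrainingConfig,
    Transition,
    fit_offline,
    fit_online,
    greedy_policy,
)
from .reward import RewardParams
from .state_space import PatientObservation, StateVector, encode_state, state_index
from .synthetic_cohort import CohortSimulator, cohort_to_transitions


class QLearningDoseRecommender(BaseEstimator):
    """Tabular Q-learning recommender for basal-insulin dose intervals.

    Parameters mirror :class:`basalq.qlearning.TrainingConfig`. ``mode``
    selects offline experience replay over the fitted trajectories
    (default) or online epsilon-greedy interaction with a simulator passed
    to :meth:`fit`.

    Attributes (after fit)
    ----------------------
    q_table_ : QTable
        Learned 306 x 6 action-value table with visit counts.
    policy_ : pandas.DataFrame
        Greedy action and visited flag per state index.
    n_sweeps_, final_max_delta_, converged_ :
        Convergence diagnostics (offline mode).
    """

    def __init__(
        self,
        alpha: float = 0.1,
        gamma: float = 0.9,
        epsilon: float = 0.1,
        n_epochs: int = 50,
        q_init: float = 0.0,
        tolerance: float = 1e-5,
        alpha_schedule: str = "constant",
        mode: str = "offline",
        n_episodes: int = 500,
        reward_params: RewardParams | None = None,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.gamma = gamma
        self.epsilon = epsilon
        self.n_epochs = n_epochs
        self.q_init = q_init
        self.tolerance = tolerance
        self.alpha_schedule = alpha_schedule
        self.mode = mode
        self.n_episodes = n_episodes
        self.reward_params = reward_params
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            alpha=self.alpha,
            gamma=self.gamma,
            epsilon=self.epsilon,
            n_epochs=self.n_epochs,
            q_init=self.q_init,
            tolerance=self.tolerance,
            seed=self.random_state,
            alpha_schedule=self.alpha_schedule,
        )

    def fit(self, X, y=None):
        """Fit the Q-table.

        ``X`` may be a visit-record DataFrame (offline), a sequence of
        :class:`Transition` (offline), or a simulator with reset/step
        (online mode).
        """
        if self.mode not in ("offline", "online"):
            raise ValueError(f"mode must be 'offline' or 'online', got {self.mode!r}")
        config = self._config()
        if self.mode == "online":
            simulator = X if hasattr(X, "step") else CohortSimulator(X)
            self.q_table_ = fit_online(simulator, config, n_episodes=self.n_episodes)
            self.convergence_ = None
        else:
            if isinstance(X, pd.DataFrame):
                rp = self.reward_params if self.reward_params is not None else RewardParams()
                transitions: Sequence[Transition] = cohort_to_transitions(X, rp)
            else:
                transitions = list(X)
            if not transitions:
                raise NoDataError("no usable transitions to fit on")
            self.q_table_, self.convergence_ = fit_offline(transitions, config)
            self.n_sweeps_ = self.convergence_.n_sweeps
            self.final_max_delta_ = self.convergence_.final_max_delta
            self.converged_ = self.convergence_.converged
        self.policy_ = greedy_policy(self.q_table_)
        return self

    def _check_fitted(self) -> QTable:
        if not hasattr(self, "q_table_"):
            raise NoDataError("estimator is not fitted; call fit() first")
        return self.q_table_

    @staticmethod
    def _states_of(X) -> list[StateVector]:
        if isinstance(X, pd.DataFrame):
            return [
                encode_state(
                    PatientObservation(
                        hba1c=row.hba1c, bmi=row.body_mass_index,
                        activity=int(row.activity_level), alcohol=int(row.alcohol_usage),
                    )
                )
                for row in X.itertuples()
            ]
        states = []
        for item in X:
            if isinstance(item, StateVector):
                states.append(item)
            elif isinstance(item, PatientObservation):
                states.append(encode_state(item))
            else:
                raise TypeError(f"cannot interpret observation {item!r}")
        return states

    def predict(self, X) -> np.ndarray:
        """Greedy action index (1..6) for each observation row or state."""
        q = self._check_fitted()
        return np.array([q.best_action(s) for s in self._states_of(X)], dtype=int)

    def predict_interval(self, X) -> list:
        """Recommended :class:`DoseInterval` for each observation."""
        from .action_space import interval_of

        return [interval_of(int(a)) for a in self.predict(X)]

    def visited(self, X) -> np.ndarray:
        """Whether each observation's state was updated during training."""
        q = self._check_fitted()
        return np.array(
            [q.visit_counts[state_index(s)].sum() > 0 for s in self._states_of(X)]
        )
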