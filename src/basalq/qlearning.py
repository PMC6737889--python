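"""Tabular Q-learning over the 306-state, 6-action dosing MDP.

The learner is plain Watkins Q-learning:

    Q(s, a) <- Q(s, a) + alpha * (r + gamma * max_a' Q(s', a') - Q(s, a))

with a zero bootstrap on terminal transitions (trajectory ends). Two fitting
modes are provided: :func:`fit_offline` replays logged experience tuples in
seeded shuffled sweeps, and :func:`fit_online` interacts with a simulator
under an epsilon-greedy behaviour policy. Greedy-policy ties break toward
the lowest action index, and states never updated are flagged unvisited.

The routines are generic over the table shape so that small synthetic MDPs
can be used to cross-check the learner against value iteration; the default
shape is the 306 x 6 dosing problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Protocol, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidActionError, InvalidStateError, NoDataError
from .action_space import N_ACTIONS
from .state_space import N_STATES, StateVector, decode_index, state_index

logger = logging.getLogger(__name__)

StateLike = Union[int, StateVector]


def _as_index(s: StateLike, n_states: int) -> int:
    if isinstance(s, StateVector):
        idx = state_index(s)
    elif isinstance(s, (int, np.integer)) and not isinstance(s, bool):
        idx = int(s)
    else:
        raise InvalidStateError(f"state must be a StateVector or integer index, got {s!r}")
    if not 0 <= idx < n_states:
        raise InvalidStateError(f"state index {idx} out of range [0, {n_states})")
    return idx


@dataclass(frozen=True)
class Transition:
    """One experience tuple (s, a, r, s') extracted from consecutive visits.

    ``terminal`` marks the end of a trajectory: the bootstrap term over the
    next state is dropped.
    """

    s: StateLike
    a: int
    r: float
    s_next: StateLike
    terminal: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError(f"reward must be finite, got {self.r!r}")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the Q-learning fit.

    alpha: learning rate in (0, 1]; ignored per-update when
        ``alpha_schedule="visit_count"``, which uses 1/n(s, a).
    gamma: discount factor in [0, 1].
    epsilon: exploration probability for online fitting.
    n_epochs: maximum number of sweeps (offline) — online fits ignore it.
    q_init: initial Q-value for every entry.
    tolerance: early-stop threshold on the max absolute Q change per sweep.
    seed: seeds both the sweep shuffling and the epsilon-greedy draws.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.1
    n_epochs: int = 50
    q_init: float = 0.0
    tolerance: float = 1e-5
    seed: int = 0
    alpha_schedule: Literal["constant", "visit_count"] = "constant"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0 <= self.epsilon <= 1:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.n_epochs < 1:
            raise ValueError(f"n_epochs must be >= 1, got {self.n_epochs}")
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.alpha_schedule not in ("constant", "visit_count"):
            raise ValueError(f"unknown alpha_schedule {self.alpha_schedule!r}")


@dataclass
class QTable:
    """Action-value table plus per-entry update counts."""

    values: np.ndarray
    visit_counts: np.ndarray

    @classmethod
    def zeros(
        cls, n_states: int = N_STATES, n_actions: int = N_ACTIONS, q_init: float = 0.0
    ) -> "QTable":
        return cls(
            values=np.full((n_states, n_actions), float(q_init)),
            visit_counts=np.zeros((n_states, n_actions), dtype=np.int64),
        )

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_actions(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "QTable":
        return QTable(self.values.copy(), self.visit_counts.copy())

    def best_action(self, s: StateLike) -> int:
        """Greedy action (1-based) at ``s``; ties break to the lowest index."""
        return int(np.argmax(self.values[_as_index(s, self.n_states)])) + 1

    def save(self, path, counts_path=None, header_lines: Sequence[str] = ()) -> None:
        """Write the table (and counts, if ``counts_path``) as commented CSV."""
        cols = [f"q{k}" for k in range(1, self.n_actions + 1)]
        for target, data, names in (
            (path, self.values, cols),
            (counts_path, self.visit_counts, [f"n{k}" for k in range(1, self.n_actions + 1)]),
        ):
            if target is None:
                continue
            df = pd.DataFrame(data, columns=names)
            df.insert(0, "state_index", np.arange(self.n_states))
            with open(target, "w") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path, counts_path=None) -> "QTable":
        df = pd.read_csv(path, comment="#").sort_values("state_index")
        values = df.drop(columns="state_index").to_numpy(dtype=float)
        if counts_path is not None:
            cdf = pd.read_csv(counts_path, comment="#").sort_values("state_index")
            counts = cdf.drop(columns="state_index").to_numpy(dtype=np.int64)
        else:
            counts = np.zeros_like(values, dtype=np.int64)
        return cls(values=values, visit_counts=counts)


@dataclass
class ConvergenceReport:
    """Summary of an offline fit: sweeps applied and per-sweep max |dQ|.

    ``target_residual_sd`` is the standard deviation of the Bellman targets
    around the converged Q-values, an estimate of the per-sample noise used
    by :func:`pessimistic_policy`.
    """

    n_sweeps: int
    final_max_delta: float
    converged: bool
    max_deltas: list[float] = field(default_factory=list)
    target_residual_sd: float = float("nan")


class Simulator(Protocol):
    """Environment protocol for online fitting."""

    def reset(self) -> StateVector: ...

    def step(self, action: int) -> tuple[StateVector, float, bool]: ...


def q_update(
    q: QTable, t: Transition, alpha: float | None = None, gamma: float = 0.9
) -> float:
    """Apply one Q-learning update in place; return the absolute Q change.

    With ``alpha=None`` the 1/n(s, a) visit-count step size is used.
    """
    s = _as_index(t.s, q.n_states)
    if not 1 <= t.a <= q.n_actions:
        raise InvalidActionError(f"action must be in [1, {q.n_actions}], got {t.a!r}")
    a = t.a - 1
    q.visit_counts[s, a] += 1
    if alpha is None:
        alpha = 1.0 / q.visit_counts[s, a]
    bootstrap = 0.0 if t.terminal else float(np.max(q.values[_as_index(t.s_next, q.n_states)]))
    delta = alpha * (t.r + gamma * bootstrap - q.values[s, a])
    q.values[s, a] += delta
    return abs(float(delta))


def select_action(
    q: QTable, s: StateLike, epsilon: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy action choice (1-based).

    Draws one uniform variate for the explore/exploit branch; with
    probability ``epsilon`` a uniformly random action is returned, otherwise
    the greedy action with ties broken to the lowest index.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    u = rng.uniform()
    if u < epsilon:
        return int(rng.integers(1, q.n_actions + 1))
    return q.best_action(s)


def fit_offline(
    transitions: Sequence[Transition],
    config: TrainingConfig = TrainingConfig(),
    n_states: int = N_STATES,
    n_actions: int = N_ACTIONS,
) -> tuple[QTable, ConvergenceReport]:
    """Learn a Q-table by seeded, shuffled experience-replay sweeps.

    Performs up to ``config.n_epochs`` full sweeps over the logged
    transitions, stopping early once the largest absolute Q change in a
    sweep drops below ``config.tolerance``.
    """
    transitions = list(transitions)
    if not transitions:
        raise NoDataError("fit_offline requires at least one transition")
    rng = np.random.default_rng(config.seed)
    q = QTable.zeros(n_states, n_actions, q_init=config.q_init)
    alpha = None if config.alpha_schedule == "visit_count" else config.alpha
    order = np.arange(len(transitions))
    max_deltas: list[float] = []
    converged = False
    for sweep in range(config.n_epochs):
        rng.shuffle(order)
        max_delta = 0.0
        for i in order:
            max_delta = max(max_delta, q_update(q, transitions[i], alpha, config.gamma))
        max_deltas.append(max_delta)
        logger.debug("sweep %d: max |dQ| = %.3g", sweep + 1, max_delta)
        if max_delta < config.tolerance:
            converged = True
            break
    residuals = np.array(
        [
            t.r
            + (0.0 if t.terminal else config.gamma * np.max(q.values[_as_index(t.s_next, n_states)]))
            - q.values[_as_index(t.s, n_states), t.a - 1]
            for t in transitions
        ]
    )
    report = ConvergenceReport(
        n_sweeps=len(max_deltas),
        final_max_delta=max_deltas[-1],
        converged=converged,
        max_deltas=max_deltas,
        target_residual_sd=float(np.std(residuals)),
    )
    return q, report


def fit_online(
    simulator: Simulator,
    config: TrainingConfig = TrainingConfig(),
    n_episodes: int = 100,
    max_steps_per_episode: int = 40,
    n_states: int = N_STATES,
    n_actions: int = N_ACTIONS,
) -> QTable:
    """Learn a Q-table by epsilon-greedy interaction with a simulator.

    Reproducibility: the agent's draws are seeded by ``config.seed``; pair
    with a simulator seeded by its own parameters for end-to-end determinism.
    """
    rng = np.random.default_rng(config.seed)
    q = QTable.zeros(n_states, n_actions, q_init=config.q_init)
    alpha = None if config.alpha_schedule == "visit_count" else config.alpha
    for _ in range(n_episodes):
        s = simulator.reset()
        for _step in range(max_steps_per_episode):
            a = select_action(q, s, config.epsilon, rng)
            s_next, r, terminal = simulator.step(a)
            q_update(q, Transition(s, a, r, s_next, terminal), alpha, config.gamma)
            if terminal:
                break
            s = s_next
    return q


def greedy_policy(q: QTable) -> pd.DataFrame:
    """Extract the greedy policy: per-state best action and a visited flag.

    Returns a DataFrame indexed by ``state_index`` with columns ``action``
    (argmax with lowest-index tie-break) and ``visited`` (whether any update
    touched the state). For the canonical 306-state table the decoded state
    components are included.
    """
    actions = np.argmax(q.values, axis=1) + 1
    visited = q.visit_counts.sum(axis=1) > 0
    df = pd.DataFrame(
        {"state_index": np.arange(q.n_states), "action": actions, "visited": visited}
    )
    if q.n_states == N_STATES and q.n_actions == N_ACTIONS:
        decoded = [decode_index(i).as_tuple() for i in range(N_STATES)]
        df[["hba1c_level", "bmi_level", "activity_level", "alcohol_level"]] = decoded
    return df.set_index("state_index")


def pessimistic_policy(q: QTable, sigma: float, n_sweeps: int = 1) -> np.ndarray:
    """Per-state best action under a lower-confidence-bound value estimate.

    Each observed entry is penalized by one standard error,
    ``sigma / sqrt(n_obs(s, a))``, where ``n_obs`` is the number of distinct
    data samples (update counts divided by ``n_sweeps`` for offline fits)
    and ``sigma`` the per-target noise (see
    ``ConvergenceReport.target_residual_sd``). Actions never observed at a
    state are excluded; a state with no observed action falls back to
    action 1. This is the standard conservative extraction rule for
    policies learned from fixed logged data, where a rarely tried action
    can win a plain argmax on sampling noise alone.

    Returns a 1-based action array of length ``n_states``.
    """
    if sigma < 0 or n_sweeps < 1:
        raise ValueError("sigma must be >= 0 and n_sweeps >= 1")
    n_obs = q.visit_counts / n_sweeps
    with np.errstate(divide="ignore"):
        adjusted = np.where(
            n_obs > 0, q.values - sigma / np.sqrt(np.maximum(n_obs, 1e-12)), -np.inf
        )
    actions = np.argmax(adjusted, axis=1) + 1
    actions[~np.isfinite(adjusted).any(axis=1)] = 1
    return actions


def value_iteration(
    rewards: np.ndarray,
    next_states: np.ndarray,
    gamma: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Exact Q* for a deterministic MDP given per-(s, a) reward and successor.

    Independent fixed-point oracle used to cross-check the sample-based
    learner on small synthetic MDPs.
    """
    q = np.zeros_like(rewards, dtype=float)
    for _ in range(max_iter):
        q_new = rewards + gamma * np.max(q[next_states], axis=-1)
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    raise RuntimeError("value iteration failed to converge")
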