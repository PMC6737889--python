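"""Synthetic visit-level cohort with a known dose-response ground truth.

No public clinical dataset accompanies this problem, so training and
policy-recovery behaviour are exercised on a simulated cohort that mimics
the structure of a basal-insulin EHR extract: by default 87 patients seen
quarterly for 10 years (40 visits), each visit recording HbA1c, BMI,
activity, alcohol use and the prescribed glargine dose.

The generator's contract is deliberately simple and fully known:

* every discrete state has a *true* dose need, linear and nondecreasing in
  each state component (higher HbA1c, higher BMI, inactivity and heavier
  alcohol use all raise the need);
* dose quality sets the HbA1c equilibrium: dosing within ``need_tolerance``
  (relative) of the need relaxes HbA1c toward a set point that degrades
  smoothly from ~5.5% (perfect dose) to ~7.5% (tolerance-edge dose), so a
  patient dosed from an uncontrolled level always improves; dosing outside
  the tolerance makes HbA1c drift up, with Gaussian noise on top;
* logged prescriptions scatter uniformly around the true need (imperfect
  prescriber), so offline learning sees both good and mediocre dosing;
* BMI follows a slow random walk; activity and alcohol stay fixed within a
  trajectory unless lifestyle switching is enabled.

This is an identification test-bed, not a physiological glucose-insulin
model: it has no meals, no intra-day dynamics and no hypoglycemia events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .action_space import DOSE_MAX, DOSE_MIN, encode_action, interval_of
from .errors import NoDataError, OutOfSupportError
from .qlearning import QTable, Transition
from .reward import DEFAULT_REWARD_PARAMS, RewardParams, compute_reward
from .state_space import (
    VISIT_COLUMNS,
    PatientObservation,
    StateVector,
    decode_index,
    encode_state,
)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults define the reference study conditions."""

    n_patients: int = 87
    visits_per_patient: int = 40
    base_need: float = 6.0          # units, at the all-lowest state
    bmi_slope: float = 1.5          # units per BMI level above 1
    hba1c_slope: float = 8.0        # units per HbA1c level above 1
    inactive_increment: float = 5.0  # units added for nonactive patients
    alcohol_slope: float = 3.0      # units per alcohol level above 1
    need_tolerance: float = 0.2     # relative dosing slack that still improves HbA1c
    hba1c_noise_sd: float = 0.3     # % HbA1c measurement/biology noise per visit
    prescriber_noise: float = 0.2   # logged doses uniform within +/-20% of need
    improvement_rate: float = 0.6   # max % HbA1c drop per visit at a perfect dose
    relapse_rate_cap: float = 0.8   # max % HbA1c rise per visit when dosing is off
    setpoint_controlled: float = 5.5  # % HbA1c equilibrium at a perfect dose
    setpoint_slope: float = 2.0     # % equilibrium rise per tolerance-unit of dose error
    relaxation_rate: float = 1.0    # fraction of the gap to the set point closed per visit;
                                    # 1.0 because quarterly visits span a full HbA1c turnover
    hba1c_floor: float = 5.0
    hba1c_ceiling: float = 12.0
    bmi_walk_sd: float = 0.15       # kg/m^2 per visit
    switch_lifestyle: bool = False  # allow rare activity/alcohol changes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.visits_per_patient < 1:
            raise ValueError("n_patients and visits_per_patient must be positive")
        slopes = (self.bmi_slope, self.hba1c_slope, self.inactive_increment, self.alcohol_slope)
        if any(s < 0 for s in slopes):
            raise ValueError("slopes must be >= 0")
        if not 0 < self.need_tolerance < 1:
            raise ValueError("need_tolerance must be in (0, 1)")
        if self.hba1c_noise_sd < 0 or self.bmi_walk_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class RawPatientState:
    """Continuous patient state carried across simulated visits."""

    hba1c: float
    bmi: float
    activity: int
    alcohol: int

    def observe(self) -> PatientObservation:
        return PatientObservation(
            hba1c=round(self.hba1c, 1), bmi=round(self.bmi, 1),
            activity=self.activity, alcohol=self.alcohol,
        )


def true_dose_need(s: StateVector, p: SimParams = SimParams()) -> float:
    """Ground-truth daily glargine need (units) for a discrete state.

    Linear in the state components and nondecreasing in each, clamped to the
    supported dose range [6, 100].
    """
    need = (
        p.base_need
        + p.hba1c_slope * (s.hba1c_level - 1)
        + p.bmi_slope * (s.bmi_level - 1)
        + p.inactive_increment * (s.activity_level - 1)
        + p.alcohol_slope * (s.alcohol_level - 1)
    )
    return float(np.clip(need, DOSE_MIN, DOSE_MAX))


def _hba1c_drift(hba1c: float, dose: float, need: float, p: SimParams) -> float:
    """Expected per-visit HbA1c change under a given dose.

    Within the tolerance band HbA1c relaxes toward a dose-quality set
    point (``setpoint_controlled`` at a perfect dose, rising by
    ``setpoint_slope`` per tolerance-unit of relative error, i.e. ~7.5% at
    the band edge with defaults), the per-visit move capped at
    ``improvement_rate`` downward. Outside the band HbA1c rises, faster the
    worse the dosing, capped at ``relapse_rate_cap``.
    """
    rel_err = abs(dose - need) / need
    target = p.setpoint_controlled + p.setpoint_slope * (rel_err / p.need_tolerance)
    drift = p.relaxation_rate * (target - hba1c)
    if rel_err <= p.need_tolerance:
        return float(np.clip(drift, -p.improvement_rate, p.relapse_rate_cap))
    # misdosing never improves control, however high the starting HbA1c
    return float(np.clip(drift, 0.0, p.relapse_rate_cap))


def simulate_transition(
    raw: RawPatientState, dose: float, p: SimParams, rng: np.random.Generator
) -> tuple[RawPatientState, StateVector]:
    """Advance a patient one visit under a given dose.

    Returns the next continuous state and its discretized StateVector.
    """
    if not DOSE_MIN <= dose <= DOSE_MAX:
        raise OutOfSupportError(f"dose {dose} outside [{DOSE_MIN:g}, {DOSE_MAX:g}]")
    need = true_dose_need(encode_state(raw.observe()), p)
    hba1c = raw.hba1c + _hba1c_drift(raw.hba1c, dose, need, p)
    if p.hba1c_noise_sd > 0:
        hba1c += rng.normal(0.0, p.hba1c_noise_sd)
    hba1c = float(np.clip(hba1c, p.hba1c_floor, p.hba1c_ceiling))
    bmi = float(np.clip(raw.bmi + rng.normal(0.0, p.bmi_walk_sd), 18.5, 35.0))
    activity, alcohol = raw.activity, raw.alcohol
    if p.switch_lifestyle:
        if rng.uniform() < 0.02:
            activity = 3 - activity
        if rng.uniform() < 0.02:
            alcohol = int(rng.integers(1, 4))
    nxt = RawPatientState(hba1c=hba1c, bmi=bmi, activity=activity, alcohol=alcohol)
    return nxt, encode_state(nxt.observe())


def _initial_state(rng: np.random.Generator, p: SimParams) -> RawPatientState:
    return RawPatientState(
        hba1c=float(rng.uniform(5.8, p.hba1c_ceiling - 0.5)),
        bmi=float(rng.uniform(18.5, 35.0)),
        activity=int(rng.integers(1, 3)),
        alcohol=int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])),
    )


def _prescribe(need: float, rng: np.random.Generator, p: SimParams) -> int:
    """Logged physician dose: true need plus relative uniform noise, whole units."""
    dose = need * (1.0 + rng.uniform(-p.prescriber_noise, p.prescriber_noise))
    return int(np.clip(round(dose), DOSE_MIN, DOSE_MAX))


def generate_cohort(p: SimParams = SimParams()) -> pd.DataFrame:
    """Generate a visit-record table for the whole synthetic cohort.

    Output columns follow the visit-file schema (`patient_id`, `visit`,
    `hba1c`, `body_mass_index`, `activity_level`, `alcohol_usage`,
    `lantus_dose`); fully determined by ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    rows = []
    for pid in range(1, p.n_patients + 1):
        raw = _initial_state(rng, p)
        for visit in range(1, p.visits_per_patient + 1):
            obs = raw.observe()
            need = true_dose_need(encode_state(obs), p)
            dose = _prescribe(need, rng, p)
            rows.append((pid, visit, obs.hba1c, obs.bmi, obs.activity, obs.alcohol, dose))
            raw, _ = simulate_transition(raw, dose, p, rng)
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def cohort_to_transitions(
    visits: pd.DataFrame,
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
) -> list[Transition]:
    """Turn trajectories into experience tuples (s, a, r, s').

    Consecutive visits of each patient form one transition; the final pair
    of a trajectory is terminal (no bootstrap). Single-visit trajectories
    are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    transitions: list[Transition] = []
    if len(visits) == 0:
        return transitions
    for pid, group in visits.groupby("patient_id", sort=False):
        group = group.sort_values("visit")
        if len(group) < 2:
            logger.warning("patient %r has a single visit; skipped", pid)
            continue
        states = [
            encode_state(
                PatientObservation(
                    hba1c=row.hba1c, bmi=row.body_mass_index,
                    activity=int(row.activity_level), alcohol=int(row.alcohol_usage),
                )
            )
            for row in group.itertuples()
        ]
        doses = group["lantus_dose"].tolist()
        n = len(states)
        for i in range(n - 1):
            transitions.append(
                Transition(
                    s=states[i],
                    a=encode_action(doses[i]),
                    r=compute_reward(
                        states[i].hba1c_level, states[i + 1].hba1c_level, reward_params
                    ),
                    s_next=states[i + 1],
                    terminal=(i == n - 2),
                )
            )
    return transitions


class CohortSimulator:
    """Online environment over the synthetic cohort dynamics.

    ``reset`` draws a fresh patient; ``step`` doses the interval midpoint of
    the chosen action, advances one visit, and rewards the HbA1c-level
    change. Episodes terminate after ``visits_per_patient`` steps.
    """

    def __init__(
        self,
        params: SimParams = SimParams(),
        reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
        seed: int | None = None,
    ) -> None:
        self.params = params
        self.reward_params = reward_params
        self._rng = np.random.default_rng(params.seed if seed is None else seed)
        self._raw: RawPatientState | None = None
        self._steps = 0

    def reset(self) -> StateVector:
        self._raw = _initial_state(self._rng, self.params)
        self._steps = 0
        return encode_state(self._raw.observe())

    def step(self, action: int) -> tuple[StateVector, float, bool]:
        if self._raw is None:
            raise NoDataError("call reset() before step()")
        interval = interval_of(action)
        dose = 0.5 * (interval.lower + interval.upper)
        before = encode_state(self._raw.observe()).hba1c_level
        self._raw, s_next = simulate_transition(self._raw, dose, self.params, self._rng)
        r = compute_reward(before, s_next.hba1c_level, self.reward_params)
        self._steps += 1
        terminal = self._steps >= self.params.visits_per_patient
        return s_next, r, terminal


def optimal_action(s: StateVector, p: SimParams = SimParams()) -> int:
    """The generator's ground-truth action: the interval holding the true need."""
    return encode_action(true_dose_need(s, p))


def policy_recovery_rate(
    q: QTable,
    p: SimParams = SimParams(),
    min_visits: int = 30,
    n_sweeps: int = 1,
    pessimism_sd: float | None = None,
) -> tuple[float, int]:
    """Fraction of well-visited states whose greedy interval covers the true need.

    A state counts as recovered when the greedy action's dose interval
    contains ``true_dose_need`` under boundary-inclusive membership (needs
    that sit exactly on an interval boundary are covered by either
    neighbour). ``min_visits`` is counted in *data* visits: update counts in
    ``q`` are divided by ``n_sweeps`` (the number of replay sweeps an
    offline fit performed) before thresholding. With ``pessimism_sd`` set,
    actions are extracted with :func:`basalq.qlearning.pessimistic_policy`
    (lower-confidence-bound rule) instead of the plain argmax.
    Returns ``(rate, n_eligible)``.
    """
    from .qlearning import pessimistic_policy

    visited = np.flatnonzero(q.visit_counts.sum(axis=1) >= min_visits * n_sweeps)
    if visited.size == 0:
        return float("nan"), 0
    if pessimism_sd is None:
        actions = {int(i): q.best_action(int(i)) for i in visited}
    else:
        all_actions = pessimistic_policy(q, pessimism_sd, n_sweeps)
        actions = {int(i): int(all_actions[i]) for i in visited}
    hits = 0
    for idx in visited:
        s = decode_index(int(idx))
        need = true_dose_need(s, p)
        if interval_of(actions[int(idx)]).contains_inclusive(need):
            hits += 1
    return hits / visited.size, int(visited.size)


def recovery_experiment(
    p: SimParams = SimParams(),
    config=None,
    min_visits: int = 30,
) -> tuple[float, int, "object"]:
    """End-to-end policy-recovery experiment on one synthetic cohort.

    Generates a cohort under ``p``, replays it offline with the 1/n(s, a)
    step-size schedule to the empirical fixed point, and extracts the
    policy with the lower-confidence-bound rule (penalty = the fit's
    estimated target noise / sqrt(n)). Returns
    ``(recovery_rate, n_eligible_states, convergence_report)`` where
    eligibility means >= ``min_visits`` data visits.
    """
    from .qlearning import TrainingConfig, fit_offline

    if config is None:
        config = TrainingConfig(alpha_schedule="visit_count", n_epochs=80, seed=p.seed)
    transitions = cohort_to_transitions(generate_cohort(p))
    q, report = fit_offline(transitions, config)
    rate, n_eligible = policy_recovery_rate(
        q, p, min_visits=min_visits, n_sweeps=report.n_sweeps,
        pessimism_sd=report.target_residual_sd,
    )
    return rate, n_eligible, report


def cohort_summary(visits: pd.DataFrame) -> str:
    """Plain-text summary: level occupancy and a dose histogram."""
    if len(visits) == 0:
        raise NoDataError("empty cohort")
    from .state_space import encode_visits

    enc = encode_visits(visits)
    lines = [
        f"patients: {visits['patient_id'].nunique()}",
        f"visits:   {len(visits)}",
        "hba1c levels: "
        + ", ".join(f"{k}={v}" for k, v in enc["hba1c_level"].value_counts().sort_index().items()),
        "bmi levels occupied: " + str(enc["bmi_level"].nunique()),
        "dose quartiles (units): "
        + np.array2string(np.percentile(visits["lantus_dose"], [0, 25, 50, 75, 100])),
    ]
    return "\n".join(lines)


def with_seed(p: SimParams, seed: int) -> SimParams:
    """Convenience: a copy of ``p`` with a different seed."""
    return replace(p, seed=seed)
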