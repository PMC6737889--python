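"""Interval-match evaluation of dose recommendations against prescribed doses.

A recommendation is an interval of glargine doses; the reference is the dose
the physician actually prescribed. A test case *matches* when the prescribed
dose lies inside the recommended interval with **both endpoints inclusive**
(the rule required to reproduce the published match labels, several of which
sit exactly on interval boundaries). The per-case error is zero on a match
and otherwise the distance from the dose to the nearest interval bound; the
harness reports the match rate and the mean of these errors.

A 60-case reference test set, transcribed from the published results table,
ships with the package (:func:`load_reference_cases`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .action_space import DoseInterval, interval_of
from .errors import NoDataError
from .state_space import StateVector, state_index

REFERENCE_FIXTURE = "table5_test_cases.csv"


@dataclass(frozen=True)
class TestCase:
    """One evaluation case: a patient state, the prescribed dose, and the
    recommended interval (as an action index)."""

    __test__ = False  # not a pytest class, despite the name

    test_number: int
    state: StateVector
    actual_dose: float
    action_index: int
    printed_match: bool | None = None

    @property
    def recommended_interval(self) -> DoseInterval:
        return interval_of(self.action_index)


@dataclass
class EvaluationReport:
    n_cases: int
    n_match: int
    mean_interval_error: float
    n_unvisited: int
    per_case: pd.DataFrame

    @property
    def match_rate(self) -> float:
        return self.n_match / self.n_cases

    def __str__(self) -> str:
        lines = [
            f"cases:               {self.n_cases}",
            f"matches:             {self.n_match} ({100 * self.match_rate:.1f}%)",
            f"mean interval error: {self.mean_interval_error:.3f} units",
        ]
        if self.n_unvisited:
            lines.append(f"unvisited states:    {self.n_unvisited}")
        return "\n".join(lines)


def dose_in_interval(dose: float, interval: DoseInterval) -> bool:
    """Boundary-inclusive membership: lower <= dose <= upper."""
    return interval.contains_inclusive(dose)


def interval_error(dose: float, interval: DoseInterval) -> float:
    """0 on a match, else distance from the dose to the nearest bound."""
    if dose_in_interval(dose, interval):
        return 0.0
    return min(abs(dose - interval.lower), abs(dose - interval.upper))


def _case_frame(cases: Sequence[TestCase], intervals: Sequence[DoseInterval]) -> pd.DataFrame:
    rows = []
    for case, interval in zip(cases, intervals):
        matched = dose_in_interval(case.actual_dose, interval)
        rows.append(
            {
                "test_number": case.test_number,
                "hba1c_level": case.state.hba1c_level,
                "bmi_level": case.state.bmi_level,
                "activity_level": case.state.activity_level,
                "alcohol_level": case.state.alcohol_level,
                "actual_dose": case.actual_dose,
                "interval": str(interval),
                "match": matched,
                "error": interval_error(case.actual_dose, interval),
            }
        )
    return pd.DataFrame(rows)


def match_rate(cases: Sequence[TestCase]) -> tuple[int, int, float, list[int]]:
    """Recompute matches against each case's own recommended interval.

    Returns ``(n_match, n_cases, rate, discrepancies)`` where
    ``discrepancies`` lists test numbers whose recomputed match flag
    disagrees with the transcribed published flag (empty when the
    transcription and the inclusive rule are mutually consistent).
    """
    cases = list(cases)
    if not cases:
        raise NoDataError("match_rate requires at least one case")
    discrepancies = []
    n_match = 0
    for case in cases:
        matched = dose_in_interval(case.actual_dose, case.recommended_interval)
        n_match += matched
        if case.printed_match is not None and matched != case.printed_match:
            discrepancies.append(case.test_number)
    return n_match, len(cases), n_match / len(cases), discrepancies


def mean_interval_error(cases: Sequence[TestCase]) -> float:
    """Mean nearest-bound distance over cases (0 for matching cases)."""
    cases = list(cases)
    if not cases:
        raise NoDataError("mean_interval_error requires at least one case")
    return sum(
        interval_error(c.actual_dose, c.recommended_interval) for c in cases
    ) / len(cases)


def evaluate_cases(cases: Sequence[TestCase]) -> EvaluationReport:
    """Score cases against their own recommended intervals."""
    cases = list(cases)
    if not cases:
        raise NoDataError("evaluate_cases requires at least one case")
    n_match, n_cases, _, _ = match_rate(cases)
    return EvaluationReport(
        n_cases=n_cases,
        n_match=n_match,
        mean_interval_error=mean_interval_error(cases),
        n_unvisited=0,
        per_case=_case_frame(cases, [c.recommended_interval for c in cases]),
    )


def evaluate_policy(policy, cases: Sequence[TestCase]) -> EvaluationReport:
    """Score a learned policy's recommendations on the cases.

    ``policy`` is either a QTable-like object with ``best_action(state)``
    and ``visit_counts`` or a callable ``StateVector -> action index``.
    Cases whose state the training never visited are still scored (the
    tie-break recommendation applies) but counted in ``n_unvisited``.
    """
    cases = list(cases)
    if not cases:
        raise NoDataError("evaluate_policy requires at least one case")
    intervals = []
    n_unvisited = 0
    for case in cases:
        if callable(policy):
            action = policy(case.state)
        else:
            action = policy.best_action(case.state)
            if policy.visit_counts[state_index(case.state)].sum() == 0:
                n_unvisited += 1
        intervals.append(interval_of(action))
    per_case = _case_frame(cases, intervals)
    return EvaluationReport(
        n_cases=len(cases),
        n_match=int(per_case["match"].sum()),
        mean_interval_error=float(per_case["error"].mean()),
        n_unvisited=n_unvisited,
        per_case=per_case,
    )


def cases_from_frame(df: pd.DataFrame) -> list[TestCase]:
    """Build test cases from a table with the reference-fixture columns."""
    cases = []
    for row in df.itertuples():
        printed = getattr(row, "printed_match", None)
        if isinstance(printed, str):
            printed = printed.strip() == "match"
        cases.append(
            TestCase(
                test_number=int(row.test_number),
                state=StateVector(
                    int(row.hba1c_level), int(row.bmi_level),
                    int(row.activity_level), int(row.alcohol_level),
                ),
                actual_dose=float(row.actual_dose),
                action_index=int(row.action_index),
                printed_match=printed,
            )
        )
    return cases


def load_reference_cases(path=None) -> list[TestCase]:
    """Load the packaged 60-case reference test set (or a user file)."""
    if path is None:
        source = resources.files("basalq.data").joinpath(REFERENCE_FIXTURE)
        with resources.as_file(source) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return cases_from_frame(df)
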