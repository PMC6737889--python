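"""Discrete patient-state representation for basal-insulin dosing.

A patient's state at a clinic visit is the 4-tuple

    (HbA1c level, BMI level, activity level, alcohol level)

with 3 x 17 x 2 x 3 = 306 possible states:

* HbA1c (glycated hemoglobin, %): 1 = well controlled (<=7), 2 = moderately
  controlled (7, 9], 3 = poorly controlled (>9).
* BMI (kg/m^2): 17 bins with edges 18.5, 19, 20, ..., 34, 35 (the first bin
  is the half-width [18.5, 19); the last is closed [34, 35]).
* Activity: 1 = active (physical activity >= 2 sessions/week), 2 = nonactive.
* Alcohol: 1 = mild/none (<2 drinks/week), 2 = moderate/high (>=2 per week),
  3 = heavy (a few drinks a day).

States are flattened to indices 0..305 in mixed-radix order with the HbA1c
level most significant, which fixes the row ordering of the Q-table.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .errors import InvalidObservationError, InvalidStateError, OutOfRangeError

logger = logging.getLogger(__name__)

N_HBA1C_LEVELS = 3
N_BMI_LEVELS = 17
N_ACTIVITY_LEVELS = 2
N_ALCOHOL_LEVELS = 3
N_STATES = N_HBA1C_LEVELS * N_BMI_LEVELS * N_ACTIVITY_LEVELS * N_ALCOHOL_LEVELS

BMI_MIN = 18.5
BMI_MAX = 35.0
#: interior bin edges; a BMI maps to level ``searchsorted(edges, bmi, 'right') + 1``
_BMI_INNER_EDGES = np.array([19.0 + k for k in range(16)])  # 19, 20, ..., 34

OutOfRangePolicy = Literal["clamp", "strict"]

#: CSV schema for visit-record files (mirrors the clinical tracking table,
#: with a patient identifier added).
VISIT_COLUMNS = [
    "patient_id",
    "visit",
    "hba1c",
    "body_mass_index",
    "activity_level",
    "alcohol_usage",
    "lantus_dose",
]


def _check_positive_number(value, name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, numbers.Real):
        raise InvalidObservationError(f"{name} must be a real number, got {value!r}")
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise InvalidObservationError(f"{name} must be finite and > 0, got {value}")
    return value


@dataclass(frozen=True)
class PatientObservation:
    """Raw measurements at one clinic visit.

    ``activity`` and ``alcohol`` are the pre-coded categories; use
    :meth:`from_raw` to build an observation from raw weekly frequencies.
    """

    hba1c: float
    bmi: float
    activity: int
    alcohol: int

    def __post_init__(self) -> None:
        _check_positive_number(self.hba1c, "hba1c")
        _check_positive_number(self.bmi, "bmi")
        if self.activity not in (1, 2):
            raise InvalidObservationError(
                f"activity category must be 1 or 2, got {self.activity!r}"
            )
        if self.alcohol not in (1, 2, 3):
            raise InvalidObservationError(
                f"alcohol category must be 1, 2 or 3, got {self.alcohol!r}"
            )

    @classmethod
    def from_raw(
        cls,
        hba1c: float,
        bmi: float,
        activity_sessions_per_week: float,
        alcohol_drinks_per_week: float = 0.0,
        daily_drinker: bool = False,
    ) -> "PatientObservation":
        """Build an observation from raw weekly frequencies."""
        return cls(
            hba1c=hba1c,
            bmi=bmi,
            activity=encode_activity(activity_sessions_per_week),
            alcohol=encode_alcohol(alcohol_drinks_per_week, daily_drinker),
        )


@dataclass(frozen=True, order=True)
class StateVector:
    """Discretized patient state: one of the 306 MDP states."""

    hba1c_level: int
    bmi_level: int
    activity_level: int
    alcohol_level: int

    def __post_init__(self) -> None:
        checks = (
            ("hba1c_level", self.hba1c_level, N_HBA1C_LEVELS),
            ("bmi_level", self.bmi_level, N_BMI_LEVELS),
            ("activity_level", self.activity_level, N_ACTIVITY_LEVELS),
            ("alcohol_level", self.alcohol_level, N_ALCOHOL_LEVELS),
        )
        for name, value, upper in checks:
            if not isinstance(value, numbers.Integral) or not 1 <= value <= upper:
                raise InvalidStateError(
                    f"{name} must be an integer in [1, {upper}], got {value!r}"
                )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hba1c_level, self.bmi_level, self.activity_level, self.alcohol_level)


def encode_hba1c(hba1c: float) -> int:
    """Map an HbA1c percentage to control level 1 (<=7), 2 ((7,9]) or 3 (>9)."""
    hba1c = _check_positive_number(hba1c, "hba1c")
    if hba1c <= 7.0:
        return 1
    if hba1c <= 9.0:
        return 2
    return 3


def encode_bmi(bmi: float, policy: OutOfRangePolicy = "clamp") -> int:
    """Map a BMI (kg/m^2) to one of the 17 levels.

    Bin edges are 18.5, 19, 20, ..., 34, 35; the last bin is closed [34, 35].
    Values outside [18.5, 35] are clamped to the nearest bin with a logged
    warning under ``policy="clamp"`` (default), or raise under ``"strict"``.
    """
    bmi = _check_positive_number(bmi, "bmi")
    if bmi < BMI_MIN or bmi > BMI_MAX:
        if policy == "strict":
            raise OutOfRangeError(
                f"BMI {bmi} outside supported range [{BMI_MIN}, {BMI_MAX}]"
            )
        logger.warning(
            "BMI %.2f outside [%.1f, %.1f]; clamping to nearest level", bmi, BMI_MIN, BMI_MAX
        )
        return 1 if bmi < BMI_MIN else N_BMI_LEVELS
    return int(np.searchsorted(_BMI_INNER_EDGES, bmi, side="right")) + 1


def encode_activity(sessions_per_week: float) -> int:
    """Map weekly physical-activity sessions to level 1 (active, >=2) or 2."""
    if isinstance(sessions_per_week, bool) or not isinstance(sessions_per_week, numbers.Real):
        raise InvalidObservationError(
            f"sessions_per_week must be a number, got {sessions_per_week!r}"
        )
    if sessions_per_week < 0:
        raise InvalidObservationError(
            f"sessions_per_week must be >= 0, got {sessions_per_week}"
        )
    return 1 if sessions_per_week >= 2 else 2


def encode_alcohol(drinks_per_week: float, daily_drinker: bool = False) -> int:
    """Map weekly alcohol consumption to level 1 (mild/none), 2 or 3 (heavy)."""
    if drinks_per_week < 0:
        raise InvalidObservationError(
            f"drinks_per_week must be >= 0, got {drinks_per_week}"
        )
    if daily_drinker:
        return 3
    return 2 if drinks_per_week >= 2 else 1


def encode_state(obs: PatientObservation, bmi_policy: OutOfRangePolicy = "clamp") -> StateVector:
    """Discretize a raw observation into a :class:`StateVector`."""
    return StateVector(
        hba1c_level=encode_hba1c(obs.hba1c),
        bmi_level=encode_bmi(obs.bmi, policy=bmi_policy),
        activity_level=obs.activity,
        alcohol_level=obs.alcohol,
    )


def state_index(s: StateVector) -> int:
    """Flat index in [0, 306) with the HbA1c level most significant."""
    a, b, c, d = s.as_tuple()
    return ((a - 1) * N_BMI_LEVELS + (b - 1)) * N_ACTIVITY_LEVELS * N_ALCOHOL_LEVELS + (
        (c - 1) * N_ALCOHOL_LEVELS + (d - 1)
    )


def decode_index(index: int) -> StateVector:
    """Inverse of :func:`state_index`."""
    if not isinstance(index, numbers.Integral) or not 0 <= index < N_STATES:
        raise InvalidStateError(f"state index must be in [0, {N_STATES}), got {index!r}")
    index = int(index)
    d = index % N_ALCOHOL_LEVELS
    index //= N_ALCOHOL_LEVELS
    c = index % N_ACTIVITY_LEVELS
    index //= N_ACTIVITY_LEVELS
    b = index % N_BMI_LEVELS
    a = index // N_BMI_LEVELS
    return StateVector(a + 1, b + 1, c + 1, d + 1)


def enumerate_states() -> Iterator[StateVector]:
    """Yield all 306 states in canonical (index) order."""
    for i in range(N_STATES):
        yield decode_index(i)


def read_visits(path) -> pd.DataFrame:
    """Read a visit-record CSV (lines starting with '#' are header comments)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidObservationError(f"visit file {path} missing columns: {missing}")
    return df


def encode_visits(visits: pd.DataFrame, bmi_policy: OutOfRangePolicy = "clamp") -> pd.DataFrame:
    """Encode a visit-record table into per-row state levels and indices.

    Returns a copy of ``visits`` with added columns ``hba1c_level``,
    ``bmi_level`` (activity/alcohol pass through) and ``state_index``.
    """
    out = visits.copy()
    states = [
        encode_state(
            PatientObservation(
                hba1c=row.hba1c,
                bmi=row.body_mass_index,
                activity=int(row.activity_level),
                alcohol=int(row.alcohol_usage),
            ),
            bmi_policy=bmi_policy,
        )
        for row in visits.itertuples()
    ]
    out["hba1c_level"] = [s.hba1c_level for s in states]
    out["bmi_level"] = [s.bmi_level for s in states]
    out["state_index"] = [state_index(s) for s in states]
    return out
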