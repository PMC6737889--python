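"""The 6 insulin-glargine (Lantus) dose intervals that form the MDP action space.

Canonical intervals, in insulin units:

    action 1: [6, 15)    action 2: [15, 20)   action 3: [20, 30)
    action 4: [30, 40)   action 5: [40, 50)   action 6: [50, 100]

Two membership semantics coexist deliberately:

* **partition** (:func:`encode_action`): lower-closed, upper-open (action 6
  closed at 100), so every logged dose in [6, 100] maps to exactly one
  training action;
* **inclusive** (:func:`basalq.evaluation.dose_in_interval`): both endpoints
  closed, the rule under which a recommended interval is scored against a
  physician-prescribed dose.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass

from .errors import InvalidActionError, OutOfSupportError

N_ACTIONS = 6
DOSE_MIN = 6.0
DOSE_MAX = 100.0


@dataclass(frozen=True)
class DoseInterval:
    """A basal-insulin dose range in insulin units."""

    lower: float
    upper: float
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidActionError(f"require lower < upper, got [{self.lower}, {self.upper}]")

    def __str__(self) -> str:
        close = "]" if self.upper_inclusive else ")"
        return f"[{self.lower:g},{self.upper:g}{close}"

    def contains_partition(self, dose: float) -> bool:
        """Half-open membership used when encoding logged doses."""
        if self.upper_inclusive:
            return self.lower <= dose <= self.upper
        return self.lower <= dose < self.upper

    def contains_inclusive(self, dose: float) -> bool:
        """Boundary-inclusive membership used when scoring recommendations."""
        return self.lower <= dose <= self.upper


INTERVALS: tuple[DoseInterval, ...] = (
    DoseInterval(6, 15),
    DoseInterval(15, 20),
    DoseInterval(20, 30),
    DoseInterval(30, 40),
    DoseInterval(40, 50),
    DoseInterval(50, 100, upper_inclusive=True),
)


def interval_of(k: int) -> DoseInterval:
    """Return the canonical interval for action index ``k`` in {1, ..., 6}."""
    if isinstance(k, bool) or not isinstance(k, numbers.Integral) or not 1 <= k <= N_ACTIONS:
        raise InvalidActionError(f"action index must be an integer in [1, {N_ACTIONS}], got {k!r}")
    return INTERVALS[int(k) - 1]


def encode_action(dose: float) -> int:
    """Map a prescribed dose (units) to its unique action index (partition semantics)."""
    if not isinstance(dose, numbers.Real) or isinstance(dose, bool):
        raise OutOfSupportError(f"dose must be a number, got {dose!r}")
    dose = float(dose)
    if dose < DOSE_MIN or dose > DOSE_MAX:
        raise OutOfSupportError(
            f"dose {dose} outside supported range [{DOSE_MIN:g}, {DOSE_MAX:g}] units"
        )
    for k, interval in enumerate(INTERVALS, start=1):
        if interval.contains_partition(dose):
            return k
    raise AssertionError("unreachable: intervals partition [6, 100]")
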