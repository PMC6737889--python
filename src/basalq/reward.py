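"""Reward for a state transition, driven by the change in HbA1c control level.

The agent is rewarded in proportion to the improvement in the discretized
HbA1c level (1 = controlled ... 3 = poorly controlled), with a bonus for
landing in the controlled band and a penalty for landing in the
uncontrolled band:

    r = w * (level_before - level_after) + bonus * 1[after == 1]
                                         - penalty * 1[after == 3]

The greedy policy is invariant to positive rescaling of the reward, so the
exact weights do not affect which dose interval the trained agent recommends
in a deterministic setting; they are exposed for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidStateError

_VALID_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class RewardParams:
    improvement_weight: float = 1.0
    controlled_bonus: float = 1.0
    uncontrolled_penalty: float = 1.0

    def __post_init__(self) -> None:
        weights = (self.improvement_weight, self.controlled_bonus, self.uncontrolled_penalty)
        if any(w < 0 for w in weights):
            raise ValueError(f"reward weights must be >= 0, got {weights}")
        if all(w == 0 for w in weights):
            raise ValueError("at least one reward weight must be positive")


DEFAULT_REWARD_PARAMS = RewardParams()


def compute_reward(
    level_before: int, level_after: int, params: RewardParams = DEFAULT_REWARD_PARAMS
) -> float:
    """Reward for moving from HbA1c level ``level_before`` to ``level_after``."""
    for name, level in (("level_before", level_before), ("level_after", level_after)):
        if level not in _VALID_LEVELS:
            raise InvalidStateError(f"{name} must be in {{1,2,3}}, got {level!r}")
    r = params.improvement_weight * (level_before - level_after)
    if level_after == 1:
        r += params.controlled_bonus
    elif level_after == 3:
        r -= params.uncontrolled_penalty
    return float(r)
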