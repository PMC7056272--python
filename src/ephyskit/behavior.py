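"""Closed-form behavioral metrics for mouse phenotyping assays.

These are the scoring formulas for novel-object recognition, acoustic
pre-pulse inhibition, Pavlovian fear conditioning, the wire-grid foot-slip
test and the social-dominance tube test. Inputs are pre-scored durations,
counts and responses; no video or startle-waveform processing happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class InteractionTimes:
    """Object-interaction durations for one novel-object trial.

    ``t_a`` is the time spent with familiar object 1 (or, on the novel
    trial, the novel object); ``t_b`` the time with familiar object 2.
    """

    t_a: float
    t_b: float

    def __post_init__(self) -> None:
        if self.t_a < 0 or self.t_b < 0:
            raise ValueError("interaction times must be non-negative")


def preference_index(times: InteractionTimes) -> float:
    """Fraction of interaction time spent with object A.

    ``t_a / (t_a + t_b)``; 0.5 means no preference. Undefined (raises)
    when the animal interacted with neither object.
    """
    total = times.t_a + times.t_b
    if total <= 0:
        raise ValueError("preference index undefined: zero total interaction time")
    return times.t_a / total


def prepulse_inhibition(prepulse_trial_response: float, test_trial_response: float) -> float:
    """Fractional startle suppression, ``1 - prepulse_trial / test_trial``.

    1 means complete inhibition; 0 means the pre-pulse had no effect.
    Can be negative if the pre-pulse facilitated the startle.
    """
    if test_trial_response <= 0:
        raise ValueError("test-pulse response must be positive")
    return 1.0 - prepulse_trial_response / test_trial_response


def corrected_freezing(test_pct: float, baseline_pct: float) -> float:
    """Freezing during the memory test minus pre-stimulus baseline freezing.

    Both arguments are percentages of time frozen in their respective
    scoring windows (contextual test vs first 2 min of training; cued-test
    last 3 min vs first 3 min). The difference may be negative.
    """
    for name, v in (("test_pct", test_pct), ("baseline_pct", baseline_pct)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be within [0, 100], got {v}")
    return test_pct - baseline_pct


def footslips_per_distance(n_slips: int, distance_m: float) -> float:
    """Foot slips on the wire grid normalized by distance traveled (slips/m)."""
    if n_slips < 0:
        raise ValueError("n_slips must be non-negative")
    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    return n_slips / distance_m


def tube_score(outcomes: Iterable[str]) -> float:
    """Mean tube-test score over bouts: a win scores 1, a loss 0.

    The assay pits each animal against three different opponents; a
    different bout count is accepted with a warning.
    """
    outcomes = list(outcomes)
    vals = []
    for o in outcomes:
        if o not in ("win", "loss"):
            raise ValueError(f"outcome must be 'win' or 'loss', got {o!r}")
        vals.append(1.0 if o == "win" else 0.0)
    if len(vals) != 3:
        warnings.warn(
            f"tube test is scored against 3 opponents; got {len(vals)} outcomes",
            stacklevel=2,
        )
    if not vals:
        raise ValueError("at least one outcome required")
    return sum(vals) / len(vals)
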