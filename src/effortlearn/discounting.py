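"""Effort-discounting staircase and subjective-value group assignment.

Participants repeatedly choose between a high-effort option at a fixed
2.00 EUR reward and a low-effort option whose reward starts at 1.00 EUR.
After a high-effort choice the low-effort offer increases on the next
trial, otherwise it decreases, and each adjustment is half the previous
one (first step 0.50 EUR). After six trials the next would-be offer is
the indifference point: the subjective value (SV) of the extra effort.
Step sizes are exactly 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625 EUR,
so SV lies on the 1/64-euro grid inside (0, 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseState",
    "DiscountResult",
    "initial_state",
    "next_offer",
    "run_staircase",
    "assign_sv_groups",
    "N_TRIALS",
    "START_OFFER",
    "FIRST_STEP",
    "FIXED_HIGH_EFFORT_OFFER",
]

N_TRIALS = 6
START_OFFER = 1.00
FIRST_STEP = 0.50
FIXED_HIGH_EFFORT_OFFER = 2.00

Choice = Literal["high_effort", "low_effort"]


class StaircaseError(RuntimeError):
    """Raised when the staircase is advanced past its six trials."""


@dataclass
class StaircaseState:
    """Evolving offer of the adaptive procedure.

    ``trial_index`` counts presented offers (1-based); ``last_step`` is
    the adjustment applied to reach the current offer, so the next
    adjustment is ``last_step / 2``.
    """

    trial_index: int = 1
    offer: float = START_OFFER
    last_step: float = 2 * FIRST_STEP
    history: list[tuple[float, str]] = field(default_factory=list)


def initial_state() -> StaircaseState:
    return StaircaseState()


def next_offer(state: StaircaseState, choice: Choice) -> StaircaseState:
    """Advance the staircase by one recorded choice.

    The offer moves up (after a high-effort choice) or down by half the
    previous step. Raises once all six trials have been consumed.
    """
    if state.trial_index > N_TRIALS:
        raise StaircaseError("staircase already completed its six trials")
    if choice not in ("high_effort", "low_effort"):
        raise ValueError(f"unknown choice {choice!r}")
    step = state.last_step / 2.0
    direction = 1.0 if choice == "high_effort" else -1.0
    return StaircaseState(
        trial_index=state.trial_index + 1,
        offer=state.offer + direction * step,
        last_step=step,
        history=state.history + [(state.offer, choice)],
    )


@dataclass(frozen=True)
class DiscountResult:
    """Indifference point of one participant."""

    sv: float
    n_trials: int
    history: tuple[tuple[float, str], ...]


def run_staircase(
    chooser: Callable[[float], Choice],
    indifference: Literal["next_offer", "last_presented"] = "next_offer",
) -> DiscountResult:
    """Run the six-trial staircase against a choice function.

    ``chooser(offer)`` returns the option taken when the low-effort
    reward is ``offer`` euros. The indifference point is, by default,
    the offer that would be presented on a seventh trial (i.e. after the
    sixth adjustment); ``indifference='last_presented'`` returns the
    sixth presented offer instead.
    """
    state = initial_state()
    for _ in range(N_TRIALS):
        state = next_offer(state, chooser(state.offer))
    if indifference == "next_offer":
        sv = state.offer
    elif indifference == "last_presented":
        sv = state.history[-1][0]
    else:
        raise ValueError(f"unknown indifference rule {indifference!r}")
    return DiscountResult(sv=float(sv), n_trials=N_TRIALS, history=tuple(state.history))


def assign_sv_groups(sv_table: pd.DataFrame, column: str = "sv") -> pd.DataFrame:
    """Median-split SV into low / high groups with -1/+1 codes.

    Values strictly below the median are 'low', strictly above 'high';
    ties at the median go to 'low'. A degenerate table where everyone
    shares one value is assigned entirely to 'low' with a warning.
    """
    if len(sv_table) < 2:
        raise ValueError("need at least two subjects for a median split")
    out = sv_table.copy()
    sv = out[column].to_numpy(dtype=float)
    med = float(np.median(sv))
    if np.all(sv == sv[0]):
        warnings.warn("all SV values identical; degenerate median split", stacklevel=2)
    group = np.where(sv > med, "high", "low")
    out["sv_group"] = group
    out["sv_code"] = np.where(group == "high", 1, -1)
    return out
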