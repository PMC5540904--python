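"""Translate LAL premotor activity into a single executed action per tick.

Each of the eight LAL modules (per hemisphere) maps to one action: module 0
-> move forward, 1 -> turn left, 2 -> turn right, 3..7 -> actions with no
spatial consequence (grooming, eating, standing still, ...).  The drive for
an action is the mean activity of its module over the two hemispheres.

Exactly one supra-threshold drive selects that action.  Two or more
supra-threshold drives are a *conflict* — an attempt to trigger mutually
exclusive commands ("turn left and right at the same time") — and arrest the
agent for the tick.  No supra-threshold drive leaves the agent motionless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .arena_world import Action
from .cx_model import N_WEDGES

DEFAULT_THETA_ACT = 0.5

#: LAL module index -> action
MODULE_ACTIONS = tuple(Action(m) for m in range(N_WEDGES))


class MotorOutcome(enum.Enum):
    SELECTED = "selected"
    CONFLICT = "conflict"
    NONE = "none"


@dataclass(frozen=True)
class MotorDecision:
    outcome: MotorOutcome
    action: "Action | None"
    drives: np.ndarray  # (8,) per-action drive

    @property
    def moves(self) -> bool:
        return self.outcome is MotorOutcome.SELECTED


def read_motor_command(lal: np.ndarray, theta_act: float = DEFAULT_THETA_ACT) -> MotorDecision:
    """Motor decision from the 16 LAL activities (left hemisphere first)."""
    lal = np.asarray(lal, dtype=float)
    if lal.shape != (2 * N_WEDGES,):
        raise ValueError("expected 16 LAL activities")
    drives = 0.5 * (lal[:N_WEDGES] + lal[N_WEDGES:])
    supra = np.flatnonzero(drives > theta_act)
    if supra.size == 1:
        return MotorDecision(MotorOutcome.SELECTED, MODULE_ACTIONS[supra[0]], drives)
    if supra.size > 1:
        return MotorDecision(MotorOutcome.CONFLICT, None, drives)
    return MotorDecision(MotorOutcome.NONE, None, drives)
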