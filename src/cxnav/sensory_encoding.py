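"""Egocentric sensory input for the simulated insect.

Two sources of information are encoded, available alone or in combination:

* body orientation — a one-hot 4-vector over N/E/S/W, an idiothetic cue;
* vision — four landmark-identity units (1.0 when the landmark shares the
  agent's sector, 0.5 anywhere else in the forward-facing visual field) and
  six binary angular-position units giving the egocentric bearing of any
  visible landmark (left, front-left, front, front-right, right, same
  sector).  Angular units cannot tell landmarks apart; identity and bearing
  must be integrated downstream.

The visual field is resolved on the 4x4 sector grid: a sector is visible
unless it lies strictly behind the agent (a 180-degree forward arc).
Internal maze walls do not occlude landmarks.  Under the intentional
condition two interoceptive bias units (e.g. hunger/thirst) are appended.
"""

from __future__ import annotations

import enum

import numpy as np

from .arena_world import AgentState, Arena, Heading, sector_of

N_BODY = 4
N_VISUAL = 4
N_ANGULAR = 6
N_BIAS = 2
N_BASE_INPUTS = N_BODY + N_VISUAL + N_ANGULAR  # 14


class Condition(str, enum.Enum):
    """Which sensory sources reach the network."""

    COMBINED = "combined"
    VISION_ONLY = "vision_only"
    ORIENTATION_ONLY = "orientation_only"
    INTENTIONAL = "intentional"

    @property
    def n_inputs(self) -> int:
        return N_BASE_INPUTS + (N_BIAS if self is Condition.INTENTIONAL else 0)


class EgocentricLabel(enum.Enum):
    FRONT_LEFT = "A"
    FRONT = "B"
    FRONT_RIGHT = "C"
    LEFT = "D"
    SAME_SECTOR = "E"
    RIGHT = "F"


#: order of the six angular-position units in the input vector
ANGULAR_ORDER = (
    EgocentricLabel.LEFT,
    EgocentricLabel.FRONT_LEFT,
    EgocentricLabel.FRONT,
    EgocentricLabel.FRONT_RIGHT,
    EgocentricLabel.RIGHT,
    EgocentricLabel.SAME_SECTOR,
)
_ANGULAR_INDEX = {label: i for i, label in enumerate(ANGULAR_ORDER)}

INPUT_LABELS = (
    "body:N",
    "body:E",
    "body:S",
    "body:W",
    "visual:1",
    "visual:2",
    "visual:3",
    "visual:4",
    "angular:left",
    "angular:front_left",
    "angular:front",
    "angular:front_right",
    "angular:right",
    "angular:same_sector",
    "bias:1",
    "bias:2",
)


def visual_field(agent: AgentState) -> dict[int, EgocentricLabel]:
    """Map each visible sector to its egocentric label.

    Sectors strictly behind the agent are absent from the mapping.
    """
    s = sector_of(agent.position)
    r, c = divmod(s - 1, 4)
    out: dict[int, EgocentricLabel] = {}
    for t in range(1, 17):
        tr, tc = divmod(t - 1, 4)
        dr, dc = tr - r, tc - c
        if agent.heading is Heading.NORTH:
            fwd, right = dr, dc
        elif agent.heading is Heading.EAST:
            fwd, right = dc, -dr
        elif agent.heading is Heading.SOUTH:
            fwd, right = -dr, -dc
        else:
            fwd, right = -dc, dr
        if fwd < 0:
            continue
        if fwd == 0:
            if right == 0:
                out[t] = EgocentricLabel.SAME_SECTOR
            else:
                out[t] = EgocentricLabel.LEFT if right < 0 else EgocentricLabel.RIGHT
        else:
            if right == 0:
                out[t] = EgocentricLabel.FRONT
            else:
                out[t] = EgocentricLabel.FRONT_LEFT if right < 0 else EgocentricLabel.FRONT_RIGHT
    return out


def encode_vision(arena: Arena, agent: AgentState) -> tuple[np.ndarray, np.ndarray]:
    """Visual-identity (4) and angular-position (6) unit activities."""
    vf = visual_field(agent)
    own = sector_of(agent.position)
    visual = np.zeros(N_VISUAL)
    angular = np.zeros(N_ANGULAR)
    for lm, sec in arena.landmarks.items():
        if sec == own:
            visual[lm - 1] = 1.0
            angular[_ANGULAR_INDEX[EgocentricLabel.SAME_SECTOR]] = 1.0
        elif sec in vf:
            visual[lm - 1] = 0.5
            angular[_ANGULAR_INDEX[vf[sec]]] = 1.0
    return visual, angular


def encode_body(agent: AgentState) -> np.ndarray:
    """One-hot body-orientation vector over (N, E, S, W)."""
    body = np.zeros(N_BODY)
    body[int(agent.heading)] = 1.0
    return body


def assemble_input(
    arena: Arena,
    agent: AgentState,
    condition: Condition = Condition.COMBINED,
    bias: "np.ndarray | tuple[float, float] | None" = None,
) -> np.ndarray:
    """Concatenated sensory vector: body (4), visual (4), angular (6)
    and, under the intentional condition, the two bias units.

    Source blocks excluded by ``condition`` are present but all-zero, so the
    vector length (and phenotype dimensionality) is fixed per condition.
    """
    condition = Condition(condition)
    body = encode_body(agent)
    visual, angular = encode_vision(arena, agent)
    if condition is Condition.VISION_ONLY:
        body = np.zeros(N_BODY)
    elif condition is Condition.ORIENTATION_ONLY:
        visual = np.zeros(N_VISUAL)
        angular = np.zeros(N_ANGULAR)
    vec = np.concatenate([body, visual, angular])
    if condition is Condition.INTENTIONAL:
        b = np.zeros(N_BIAS) if bias is None else np.asarray(bias, dtype=float)
        if b.shape != (N_BIAS,):
            raise ValueError("bias must have exactly two entries")
        if (b != 0).sum() > 1:
            raise ValueError("at most one interoceptive bias may be active")
        vec = np.concatenate([vec, b])
    elif bias is not None:
        raise ValueError("bias input is only defined under the intentional condition")
    return vec


def input_table(arena: Arena, condition: Condition = Condition.COMBINED) -> np.ndarray:
    """Lookup table of the 14 base input activities, shape (16, 4, 14).

    Sensory input depends only on (sector, heading, landmark layout), never on
    the within-sector position, so one representative location per sector
    suffices.  Bias units are appended at run time by the caller.
    """
    condition = Condition(condition)
    table = np.zeros((16, 4, N_BASE_INPUTS))
    base = Condition.COMBINED if condition is Condition.INTENTIONAL else condition
    from .arena_world import Location  # local import to keep module surface tidy

    for sec in range(1, 17):
        r, c = divmod(sec - 1, 4)
        loc = Location(c * 10 + 5, r * 10 + 5)
        for h in Heading:
            table[sec - 1, int(h)] = assemble_input(arena, AgentState(loc, h), base)
    return table
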