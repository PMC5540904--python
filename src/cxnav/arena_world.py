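"""Discrete 2-D arenas for the simulated insect.

All arenas are 40x40 grids of unit *locations*, partitioned into 16 sectors
of 10x10.  Coordinates are 1-based: ``x`` runs west to east, ``y`` runs south
to north, so a forward step while heading North increments ``y``.  Walls are
non-walkable grid cells; a blocked forward command is silently ignored (the
agent keeps its position but the decision tick is still consumed).

Three canonical arenas are provided: an ``open`` arena, a ``simple_maze``
with one internal wall pierced by a sector-wide passage, and a
``complex_maze`` whose internal walls force a minimum of five turns from the
start region to either target area.
"""

from __future__ import annotations

import enum
import math
from collections import deque
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

import numpy as np

GRID_SIZE = 40
SECTOR_SIZE = 10
N_SECTORS = 16

START_SECTOR = 1
TARGET1_SECTOR = 14
TARGET2_SECTOR = 16

#: corner name -> sector id of the corresponding 10x10 corner sector
CORNER_SECTORS = {"SW": 1, "SE": 4, "NE": 16, "NW": 13}

#: default landmark placement; the assignment is configurable in make_arena
DEFAULT_LANDMARK_CORNERS: Mapping[int, str] = {1: "SW", 2: "SE", 3: "NE", 4: "NW"}

#: grid cell (x, y) used to annotate each corner landmark in the ASCII format
_CORNER_CELLS = {"SW": (1, 1), "SE": (40, 1), "NE": (40, 40), "NW": (1, 40)}


class ArenaKind(str, enum.Enum):
    OPEN = "open"
    SIMPLE_MAZE = "simple_maze"
    COMPLEX_MAZE = "complex_maze"


class Heading(enum.IntEnum):
    """Cardinal body orientation, N-E-S-W in clockwise order."""

    NORTH = 0
    EAST = 1
    SOUTH = 2
    WEST = 3

    def turned_left(self) -> "Heading":
        return Heading((self - 1) % 4)

    def turned_right(self) -> "Heading":
        return Heading((self + 1) % 4)


#: (dx, dy) of a forward step, indexed by Heading
STEP = {
    Heading.NORTH: (0, 1),
    Heading.EAST: (1, 0),
    Heading.SOUTH: (0, -1),
    Heading.WEST: (-1, 0),
}


class Action(enum.IntEnum):
    """The eight premotor commands; only the first three move the agent."""

    FORWARD = 0
    TURN_LEFT = 1
    TURN_RIGHT = 2
    NULL1 = 3
    NULL2 = 4
    NULL3 = 5
    NULL4 = 6
    NULL5 = 7


MOVING_ACTIONS = (Action.FORWARD, Action.TURN_LEFT, Action.TURN_RIGHT)


class Location(NamedTuple):
    x: int
    y: int


@dataclass(frozen=True)
class AgentState:
    position: Location
    heading: Heading


def sector_of(loc: Location) -> int:
    """Sector id (1..16) of a location, row-major from the southwest corner."""
    x, y = loc
    if not (1 <= x <= GRID_SIZE and 1 <= y <= GRID_SIZE):
        raise ValueError(f"location out of range: {loc!r}")
    return 4 * ((y - 1) // SECTOR_SIZE) + (x - 1) // SECTOR_SIZE + 1


def sector_locations(sector: int) -> frozenset[Location]:
    """The 100 locations of a sector."""
    if not (1 <= sector <= N_SECTORS):
        raise ValueError(f"sector out of range: {sector}")
    r, c = divmod(sector - 1, 4)
    return frozenset(
        Location(c * SECTOR_SIZE + i, r * SECTOR_SIZE + j)
        for i in range(1, SECTOR_SIZE + 1)
        for j in range(1, SECTOR_SIZE + 1)
    )


@dataclass(frozen=True)
class Arena:
    """A walkable mask plus the fixed task geometry (start, targets, landmarks).

    ``walkable`` is indexed ``[y - 1, x - 1]``. ``landmarks`` maps landmark id
    (1..4) to the sector it occupies.
    """

    kind: ArenaKind
    walkable: np.ndarray
    landmarks: Mapping[int, int]
    start_region: frozenset[Location]
    target1: frozenset[Location]
    target2: frozenset[Location]

    def __post_init__(self) -> None:
        if self.walkable.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError("walkable mask must be 40x40")

    def is_walkable(self, loc: Location) -> bool:
        x, y = loc
        return 1 <= x <= GRID_SIZE and 1 <= y <= GRID_SIZE and bool(self.walkable[y - 1, x - 1])

    def target(self, target_id: int) -> frozenset[Location]:
        if target_id == 1:
            return self.target1
        if target_id == 2:
            return self.target2
        raise ValueError(f"invalid target id: {target_id!r}")

    @property
    def n_walkable(self) -> int:
        return int(self.walkable.sum())


def _build_arena(kind: ArenaKind, walkable: np.ndarray, landmarks: Mapping[int, int]) -> Arena:
    return Arena(
        kind=kind,
        walkable=walkable,
        landmarks=dict(landmarks),
        start_region=sector_locations(START_SECTOR),
        target1=sector_locations(TARGET1_SECTOR),
        target2=sector_locations(TARGET2_SECTOR),
    )


def _landmarks_from_corners(corners: Mapping[int, str]) -> dict[int, int]:
    if sorted(corners) != [1, 2, 3, 4] or sorted(corners.values()) != sorted(CORNER_SECTORS):
        raise ValueError("landmark assignment must map ids 1-4 onto the four corners")
    return {lm: CORNER_SECTORS[corner] for lm, corner in corners.items()}


def _wall_cells_simple() -> list[tuple[int, int]]:
    # horizontal wall at y=21 with a one-sector-wide passage at x in [21, 30]
    return [(x, 21) for x in range(1, 21)] + [(x, 21) for x in range(31, 41)]


_ARENA_CACHE: dict[tuple, Arena] = {}


def make_arena(
    kind: ArenaKind | str,
    landmark_corners: Mapping[int, str] | None = None,
) -> Arena:
    """Construct one of the three canonical arenas.

    ``landmark_corners`` optionally reassigns landmark ids to corners; the
    default places landmark 1 SW, 2 SE, 3 NE and 4 NW.
    """
    try:
        kind = ArenaKind(kind)
    except ValueError:
        raise ValueError(f"unknown arena kind: {kind!r}") from None
    corners = dict(landmark_corners or DEFAULT_LANDMARK_CORNERS)
    key = (kind, tuple(sorted(corners.items())))
    if key in _ARENA_CACHE:
        return _ARENA_CACHE[key]

    landmarks = _landmarks_from_corners(corners)
    if kind is ArenaKind.OPEN:
        arena = _build_arena(kind, np.ones((GRID_SIZE, GRID_SIZE), dtype=bool), landmarks)
    elif kind is ArenaKind.SIMPLE_MAZE:
        walk = np.ones((GRID_SIZE, GRID_SIZE), dtype=bool)
        for x, y in _wall_cells_simple():
            walk[y - 1, x - 1] = False
        arena = _build_arena(kind, walk, landmarks)
    else:
        text = resources.files("cxnav").joinpath("data/complex_maze.txt").read_text()
        arena = arena_from_text(text)
        if landmark_corners is not None:
            arena = _build_arena(kind, arena.walkable, landmarks)
        _validate_complex(arena)
    _ARENA_CACHE[key] = arena
    return arena


def _validate_complex(arena: Arena) -> None:
    for tid in (1, 2):
        turns = min_turns(arena, arena.start_region, arena.target(tid), Heading.EAST)
        if turns != 5:
            raise RuntimeError(
                f"complex maze layout invalid: min turns to target {tid} is {turns}, expected 5"
            )


def execute_action(arena: Arena, agent: AgentState, action: Action) -> AgentState:
    """Apply one motor command; blocked forward moves are silent no-ops."""
    if action is Action.FORWARD:
        dx, dy = STEP[agent.heading]
        dest = Location(agent.position.x + dx, agent.position.y + dy)
        if arena.is_walkable(dest):
            return AgentState(dest, agent.heading)
        return agent
    if action is Action.TURN_LEFT:
        return AgentState(agent.position, agent.heading.turned_left())
    if action is Action.TURN_RIGHT:
        return AgentState(agent.position, agent.heading.turned_right())
    return agent


def in_target(arena: Arena, agent: AgentState, target_id: int) -> bool:
    return agent.position in arena.target(target_id)


def min_turns(
    arena: "Arena | np.ndarray",
    starts: Iterable[Location],
    targets: Iterable[Location],
    initial_heading: Heading = Heading.EAST,
) -> float:
    """Minimum number of Turn actions needed from any start to any target.

    0-1 breadth-first search over (location, heading) states: forward edges
    cost 0 turns, turn edges cost 1.  Returns ``math.inf`` when no target is
    reachable.  Works on any rectangular walkable mask, not just 40x40.
    """
    walkable = arena.walkable if isinstance(arena, Arena) else np.asarray(arena, dtype=bool)
    height, width = walkable.shape
    starts = [Location(*s) for s in starts]
    target_set = {Location(*t) for t in targets}
    if not starts or not target_set:
        raise ValueError("start and target sets must be non-empty")
    for loc in list(target_set) + starts:
        if not (1 <= loc.x <= width and 1 <= loc.y <= height) or not walkable[loc.y - 1, loc.x - 1]:
            raise ValueError(f"location {loc!r} is not walkable")

    target_mask = np.zeros((height, width), dtype=bool)
    for t in target_set:
        target_mask[t.y - 1, t.x - 1] = True

    INF = np.iinfo(np.int32).max
    dist = np.full((height, width, 4), INF, dtype=np.int32)
    dq: deque[tuple[int, int, int]] = deque()
    h0 = int(initial_heading)
    for s in starts:
        if dist[s.y - 1, s.x - 1, h0] != 0:
            dist[s.y - 1, s.x - 1, h0] = 0
            dq.append((s.x, s.y, h0))

    while dq:
        x, y, h = dq.popleft()
        d = int(dist[y - 1, x - 1, h])
        if target_mask[y - 1, x - 1]:
            return d
        # forward: cost 0
        dx, dy = STEP[Heading(h)]
        nx, ny = x + dx, y + dy
        if 1 <= nx <= width and 1 <= ny <= height and walkable[ny - 1, nx - 1]:
            if d < dist[ny - 1, nx - 1, h]:
                dist[ny - 1, nx - 1, h] = d
                dq.appendleft((nx, ny, h))
        # turns: cost 1
        for h2 in ((h - 1) % 4, (h + 1) % 4):
            if d + 1 < dist[y - 1, x - 1, h2]:
                dist[y - 1, x - 1, h2] = d + 1
                dq.append((x, y, h2))
    return math.inf


# --------------------------------------------------------------------------
# ASCII arena format
#
# Header line "kind: <kind>", then 40 lines of 40 characters, northernmost
# row first.  '.' = walkable, '#' = wall cell, digits '1'-'4' mark the corner
# landmark cells (annotation only; the cell itself is walkable).


def arena_to_text(arena: Arena) -> str:
    sector_to_corner = {sec: corner for corner, sec in CORNER_SECTORS.items()}
    marker: dict[tuple[int, int], str] = {}
    for lm, sec in arena.landmarks.items():
        marker[_CORNER_CELLS[sector_to_corner[sec]]] = str(lm)
    lines = [f"kind: {arena.kind.value}"]
    for y in range(GRID_SIZE, 0, -1):
        row = []
        for x in range(1, GRID_SIZE + 1):
            if not arena.walkable[y - 1, x - 1]:
                row.append("#")
            else:
                row.append(marker.get((x, y), "."))
        lines.append("".join(row))
    return "\n".join(lines) + "\n"


def arena_from_text(text: str) -> Arena:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("kind:"):
        raise ValueError("arena text must start with a 'kind: <kind>' header")
    kind = ArenaKind(lines[0].split(":", 1)[1].strip())
    rows = lines[1:]
    if len(rows) != GRID_SIZE or any(len(r) != GRID_SIZE for r in rows):
        raise ValueError("arena body must be 40 lines of 40 characters")
    walk = np.ones((GRID_SIZE, GRID_SIZE), dtype=bool)
    cell_to_corner = {cell: corner for corner, cell in _CORNER_CELLS.items()}
    corners: dict[int, str] = {}
    for i, row in enumerate(rows):
        y = GRID_SIZE - i
        for x, ch in enumerate(row, start=1):
            if ch == "#":
                walk[y - 1, x - 1] = False
            elif ch in "1234":
                corners[int(ch)] = cell_to_corner[(x, y)]
            elif ch != ".":
                raise ValueError(f"invalid arena character {ch!r} at ({x}, {y})")
    landmarks = _landmarks_from_corners(corners)
    return _build_arena(kind, walk, landmarks)


def save_arena(arena: Arena, path) -> None:
    with open(path, "w") as fh:
        fh.write(arena_to_text(arena))


def load_arena(path) -> Arena:
    with open(path) as fh:
        return arena_from_text(fh.read())
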