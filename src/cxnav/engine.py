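"""Vectorized batch simulation of closed-loop trials.

Runs many (phenotype, start location) trials in lockstep: one array row per
trial, with the network integrated by dense linear algebra and the
arena interaction (wall blocking, turning, target entry) applied with
integer index arithmetic.  Because the sensory input depends only on
(sector, heading) — plus the bias phase under the intentional condition —
inputs are read from a precomputed 16 x 4 lookup table.

A trial whose agent has stopped moving *and* whose potentials have reached a
fixed point can never act differently again (the dynamics are deterministic
and autonomous under static input), so it is pruned early as a failure; this
is exact, not an approximation, up to the 1e-10 fixed-point tolerance.

``cxnav.experiments.run_trial`` wraps this engine with batch size 1 and full
trace recording; its step-by-step semantics are mirrored (and tested)
against the scalar operations in ``cx_model`` / ``motor_readout`` /
``arena_world``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena_world import Arena, GRID_SIZE, Heading, sector_of, Location
from .cx_model import (
    ArchConfig,
    DEFAULT_ARCH,
    DynamicsConfig,
    N_EB,
    N_UNITS,
    N_WEDGES,
    build_cx,
)
from .motor_readout import DEFAULT_THETA_ACT
from .sensory_encoding import Condition, N_BASE_INPUTS, input_table

#: outcome codes in recorded traces
OUTCOME_NONE, OUTCOME_SELECTED, OUTCOME_CONFLICT = 0, 1, 2

_FIXED_POINT_TOL = 1e-10

# forward displacement by heading code (N, E, S, W)
_DX = np.array([0, 1, 0, -1], dtype=np.int64)
_DY = np.array([1, 0, -1, 0], dtype=np.int64)


@dataclass
class BatchResult:
    """Per-trial outcomes of a batch run.

    ``reached`` is 0 (no target) / 1 / 2 for sensory-driven trials.  Under
    the intentional condition it records sequence progress: 1 = reached
    target 1 under bias 1, 2 = completed the full target-1-then-target-2
    sequence; ``completed`` flags the latter.
    """

    n: int
    intentional: bool
    reached: np.ndarray  # int8 (n,)
    time_to_target: np.ndarray  # float (n,), NaN when never reached
    time_to_target1: np.ndarray  # float (n,), intentional phase-1 times
    error: np.ndarray  # bool (n,), non-finite dynamics
    trace: "dict[str, np.ndarray] | None" = None

    @property
    def completed(self) -> np.ndarray:
        return self.reached == 2 if self.intentional else self.reached > 0

    def success(self, target_id: int) -> np.ndarray:
        if self.intentional:
            raise ValueError("per-target success is undefined for intentional runs")
        return self.reached == target_id


def _expand_weights(weights: np.ndarray, n_inputs: int) -> np.ndarray:
    """(B, n_inputs, 32) hemisphere-shared or (B, n_inputs, 64) -> (B, n_inputs, 64)."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 3 or weights.shape[1] != n_inputs:
        raise ValueError(f"weights must have shape (B, {n_inputs}, 32|64)")
    if weights.shape[2] == N_UNITS:
        return weights
    if weights.shape[2] != 32:
        raise ValueError("last weight axis must be 32 (shared) or 64")
    eb, lal = weights[:, :, :24], weights[:, :, 24:]
    return np.concatenate([eb, eb, lal, lal], axis=2)


def simulate_batch(
    arena: Arena,
    condition: Condition,
    weights: np.ndarray,
    start_x: np.ndarray,
    start_y: np.ndarray,
    cfg: "DynamicsConfig | None" = None,
    *,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
    bias: "np.ndarray | None" = None,
    duration: "float | None" = None,
    record: bool = False,
    prune: bool = True,
) -> BatchResult:
    """Run one trial per row of ``weights`` / ``start_x`` / ``start_y``.

    ``bias`` is an optional shared (64,) basal-activity vector (EB
    manipulations).  ``duration`` overrides ``cfg.trial_duration`` (the
    intentional condition uses its own total budget).  With ``record=True``
    per-tick activations, positions and decisions are kept (small batches).
    """
    condition = Condition(condition)
    cfg = cfg or DynamicsConfig()
    intentional = condition is Condition.INTENTIONAL
    n_in = condition.n_inputs

    w_full = _expand_weights(weights, n_in)
    n_total = w_full.shape[0]
    x = np.asarray(start_x, dtype=np.int64).copy()
    y = np.asarray(start_y, dtype=np.int64).copy()
    if x.shape != (n_total,) or y.shape != (n_total,):
        raise ValueError("start coordinate arrays must match the batch size")

    # padded [x, y] grids, 1-based coordinates with a non-walkable border
    walk = np.zeros((GRID_SIZE + 2, GRID_SIZE + 2), dtype=bool)
    walk[1:-1, 1:-1] = arena.walkable.T
    target_grid = np.zeros((GRID_SIZE + 2, GRID_SIZE + 2), dtype=np.int8)
    for tid in (1, 2):
        for loc in arena.target(tid):
            target_grid[loc.x, loc.y] = tid
    sector_grid = np.zeros((GRID_SIZE + 2, GRID_SIZE + 2), dtype=np.int64)
    for xi in range(1, GRID_SIZE + 1):
        for yi in range(1, GRID_SIZE + 1):
            sector_grid[xi, yi] = sector_of(Location(xi, yi))

    for loc in zip(x, y):
        if not walk[loc]:
            raise ValueError(f"start location {loc} is not walkable")

    lookup = input_table(arena, condition)  # (16, 4, 14)
    wrec_t = np.ascontiguousarray(build_cx(arch).recurrent.T)
    b_vec = np.zeros(N_UNITS) if bias is None else np.asarray(bias, dtype=float)

    steps = cfg.steps_per_decision
    alpha = np.exp(-cfg.dt / cfg.tau_g)
    euler = cfg.integrator == "euler"
    h_coef = cfg.dt / cfg.tau_g
    n_ticks = cfg.n_decisions(duration)

    # mutable per-trial state (compacted as trials finish)
    gidx = np.arange(n_total)
    u = np.zeros((n_total, N_UNITS))
    h = np.full(n_total, int(Heading.EAST), dtype=np.int64)
    phase = np.zeros(n_total, dtype=np.int8)
    w_live = w_full

    reached = np.zeros(n_total, dtype=np.int8)
    t_hit = np.full(n_total, np.nan)
    t_hit1 = np.full(n_total, np.nan)
    error = np.zeros(n_total, dtype=bool)

    tr: "dict[str, list] | None" = None
    if record:
        tr = {k: [] for k in ("act", "x_pos", "y_pos", "heading", "action", "outcome", "phase")}

    live = np.ones(n_total, dtype=bool)
    for tick in range(n_ticks):
        if not live.any():
            break
        sec = sector_grid[x, y] - 1
        xin = lookup[sec, h]
        if intentional:
            xin = np.concatenate([xin, (phase == 0)[:, None] * 1.0, (phase == 1)[:, None] * 1.0], axis=1)
        sens = np.matmul(xin[:, None, :], w_live)[:, 0, :] + b_vec

        u_prev = u.copy() if prune else None
        for _ in range(steps):
            net = np.maximum(np.tanh(u), 0.0) @ wrec_t + sens
            if euler:
                u = u + h_coef * (net - u)
            else:
                u = net + (u - net) * alpha
        y_act = np.maximum(np.tanh(u), 0.0)

        finite = np.isfinite(u).all(axis=1)
        lal = y_act[:, N_EB:]
        drives = 0.5 * (lal[:, :N_WEDGES] + lal[:, N_WEDGES:])
        supra = drives > theta_act
        nsupra = supra.sum(axis=1)
        selected = (nsupra == 1) & live & finite
        action = np.where(selected, supra.argmax(axis=1), -1)

        fwd = selected & (action == 0)
        nx = x + _DX[h]
        ny = y + _DY[h]
        ok = fwd & walk[np.clip(nx, 0, GRID_SIZE + 1), np.clip(ny, 0, GRID_SIZE + 1)]
        x = np.where(ok, nx, x)
        y = np.where(ok, ny, y)
        tl = selected & (action == 1)
        trn = selected & (action == 2)
        h = np.where(tl, (h - 1) % 4, h)
        h = np.where(trn, (h + 1) % 4, h)
        changed = ok | tl | trn

        t_now = (tick + 1) * cfg.decision_interval
        tg = target_grid[x, y]
        if intentional:
            adv = live & finite & (phase == 0) & (tg == 1)
            phase = np.where(adv, 1, phase)
            reached[gidx[adv]] = 1
            t_hit1[gidx[adv]] = t_now
            done = live & finite & (phase == 1) & (tg == 2)
            reached[gidx[done]] = 2
            t_hit[gidx[done]] = t_now
        else:
            done = live & finite & (tg > 0)
            reached[gidx[done]] = tg[done]
            t_hit[gidx[done]] = t_now

        bad = live & ~finite
        error[gidx[bad]] = True

        if record:
            tr["act"].append(y_act.copy())
            tr["x_pos"].append(x.copy())
            tr["y_pos"].append(y.copy())
            tr["heading"].append(h.copy())
            tr["action"].append(action.copy())
            out = np.where(nsupra == 1, OUTCOME_SELECTED,
                           np.where(nsupra > 1, OUTCOME_CONFLICT, OUTCOME_NONE))
            tr["outcome"].append(out.astype(np.int8))
            tr["phase"].append(phase.copy())

        drop = done | bad
        if prune and u_prev is not None:
            frozen = live & ~changed & (np.abs(u - u_prev).max(axis=1) < _FIXED_POINT_TOL)
            drop = drop | frozen
        live = live & ~drop

        # compact state arrays once a sizable fraction of trials has finished
        if not record and live.size and live.mean() < 0.9:
            keep = live
            gidx, u, x, y, h, phase, w_live = (
                gidx[keep], u[keep], x[keep], y[keep], h[keep], phase[keep], w_live[keep],
            )
            live = np.ones(gidx.size, dtype=bool)

    trace = None
    if record and tr is not None:
        trace = {k: np.stack(v) if v else np.empty((0, n_total)) for k, v in tr.items()}
    return BatchResult(
        n=n_total,
        intentional=intentional,
        reached=reached,
        time_to_target=t_hit,
        time_to_target1=t_hit1,
        error=error,
        trace=trace,
    )
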