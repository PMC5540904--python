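"""Experiment harness: single trials, Monte-Carlo phenotype searches,
EB-manipulation comparisons and intentional (sequential-goal) navigation.

A *behavioral phenotype* is one sampled configuration of input->EB/LAL
weights; the search draws phenotypes i.i.d. uniform on [-1, 1], runs one
trial per phenotype from a random start location, and reports the number of
successful navigations per million attempts.  Per-sample randomness is
derived from ``SeedSequence((master_seed, sample_index))`` so results are
independent of batch partitioning and fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arena_world import (
    Action,
    Arena,
    ArenaKind,
    Heading,
    Location,
    make_arena,
)
from .cx_model import (
    DEFAULT_ARCH,
    ArchConfig,
    DynamicsConfig,
    N_EB,
    N_LAYERS,
    N_WEDGES,
    Phenotype,
    manipulation_bias,
)
from .engine import OUTCOME_CONFLICT, OUTCOME_NONE, OUTCOME_SELECTED, simulate_batch
from .motor_readout import DEFAULT_THETA_ACT
from .sensory_encoding import Condition

INITIAL_HEADING = Heading.EAST
INTENTIONAL_BUDGET_S = 60.0  # total budget; up to half per goal phase

_HEADING_LETTERS = "NESW"
_OUTCOME_NAMES = {OUTCOME_NONE: "none", OUTCOME_SELECTED: "selected", OUTCOME_CONFLICT: "conflict"}


def _start_locations(arena: Arena) -> np.ndarray:
    """The 100 start locations in a fixed (sorted) order, shape (100, 2)."""
    return np.array(sorted(arena.start_region), dtype=np.int64)


def sample_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-style per-sample seed, independent of batch partitioning."""
    return np.random.SeedSequence((int(master_seed), int(index)))


def _draw_sample(
    master_seed: int, index: int, condition: Condition, starts: np.ndarray
) -> tuple[np.ndarray, int, int]:
    rng = np.random.default_rng(sample_seed(master_seed, index))
    weights = rng.uniform(-1.0, 1.0, size=(condition.n_inputs, 32))
    sx, sy = starts[rng.integers(len(starts))]
    return weights, int(sx), int(sy)


# --------------------------------------------------------------------------
# Single trials


@dataclass
class TrialResult:
    """Outcome and full per-tick record of a single 30 s trial."""

    arena_kind: str
    condition: str
    start: Location
    success: dict
    reached_target: "int | None"
    time_to_target: "float | None"
    failed_error: bool
    trajectory: pd.DataFrame  # tick, time_s, x, y, heading, action, outcome
    activity: pd.DataFrame  # time_s + EB wedge means per hemisphere + LAL units
    phenotype_seed: object = None


def run_trial(
    arena: Arena,
    phenotype: Phenotype,
    cfg: "DynamicsConfig | None" = None,
    seed: "int | None" = None,
    *,
    start: "Location | None" = None,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
    bias: "np.ndarray | None" = None,
    duration: "float | None" = None,
) -> TrialResult:
    """Run one closed-loop trial and record trajectory and activity traces.

    The start location is drawn uniformly from the 100-location start region
    (``seed``) unless given explicitly; the initial heading is East and the
    initial potentials are zero.  Deterministic given (phenotype, start).
    """
    cfg = cfg or DynamicsConfig()
    condition = phenotype.condition
    if start is None:
        rng = np.random.default_rng(seed)
        starts = _start_locations(arena)
        start = Location(*map(int, starts[rng.integers(len(starts))]))
    if condition is Condition.INTENTIONAL and duration is None:
        duration = INTENTIONAL_BUDGET_S

    weights = phenotype.input_matrix()[None, :, :]
    res = simulate_batch(
        arena, condition, weights,
        np.array([start.x]), np.array([start.y]),
        cfg, arch=arch, theta_act=theta_act, bias=bias, duration=duration,
        record=True, prune=False,
    )
    trace = res.trace
    n_ticks = trace["x_pos"].shape[0]
    time_s = (np.arange(n_ticks) + 1) * cfg.decision_interval
    # cut the record at target entry (the trial terminates there)
    t_end = res.time_to_target[0]
    last = n_ticks if np.isnan(t_end) else int(round(t_end / cfg.decision_interval))
    sl = slice(0, last)

    action_names = np.array([a.name for a in Action] + [""])
    trajectory = pd.DataFrame(
        {
            "tick": np.arange(last),
            "time_s": time_s[sl],
            "x": trace["x_pos"][sl, 0],
            "y": trace["y_pos"][sl, 0],
            "heading": [_HEADING_LETTERS[int(v)] for v in trace["heading"][sl, 0]],
            "action": action_names[trace["action"][sl, 0]],
            "outcome": [_OUTCOME_NAMES[int(v)] for v in trace["outcome"][sl, 0]],
        }
    )
    act = trace["act"][sl, 0, :]
    eb = act[:, :N_EB].reshape(last, 2, N_WEDGES, N_LAYERS).mean(axis=3)
    cols = {"time_s": time_s[sl]}
    for hi, hl in enumerate("LR"):
        for w in range(N_WEDGES):
            cols[f"eb{hl}_w{w}"] = eb[:, hi, w]
    for hi, hl in enumerate("LR"):
        for m in range(N_WEDGES):
            cols[f"lal{hl}_m{m}"] = act[:, N_EB + hi * N_WEDGES + m]
    activity = pd.DataFrame(cols)

    reached = int(res.reached[0])
    if condition is Condition.INTENTIONAL:
        success = {"sequence": bool(res.completed[0]), "target1": reached >= 1}
        reached_target = None if reached == 0 else reached
    else:
        success = {1: reached == 1, 2: reached == 2}
        reached_target = reached or None
    return TrialResult(
        arena_kind=arena.kind.value,
        condition=condition.value,
        start=start,
        success=success,
        reached_target=reached_target,
        time_to_target=None if np.isnan(t_end) else float(t_end),
        failed_error=bool(res.error[0]),
        trajectory=trajectory,
        activity=activity,
        phenotype_seed=phenotype.seed,
    )


# --------------------------------------------------------------------------
# Monte-Carlo phenotype search


@dataclass
class SearchResult:
    """Counts of successful behavioral phenotypes in a random search."""

    arena_kind: str
    condition: str
    target_id: "int | None"
    n: int
    master_seed: int
    successes: dict  # {"target1": int, "target2": int} or {"sequence": int, ...}
    hits: list = field(default_factory=list)  # per-success records
    n_errors: int = 0

    def ratio_per_million(self, key: "str | None" = None) -> float:
        if key is None:
            key = self._headline_key()
        return self.successes[key] / self.n * 1e6

    def _headline_key(self) -> str:
        if "sequence" in self.successes:
            return "sequence"
        if self.target_id is not None:
            return f"target{self.target_id}"
        return "any"

    def to_dict(self) -> dict:
        return {
            "arena": self.arena_kind,
            "condition": self.condition,
            "target_id": self.target_id,
            "n": self.n,
            "master_seed": self.master_seed,
            "successes": dict(self.successes),
            "ratios_per_million": {k: v / self.n * 1e6 for k, v in self.successes.items()},
            "n_errors": self.n_errors,
            "hits": list(self.hits),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _batched_indices(n: int, batch_size: int):
    for lo in range(0, n, batch_size):
        yield range(lo, min(lo + batch_size, n))


def monte_carlo_search(
    arena_kind: "ArenaKind | str",
    condition: "Condition | str",
    target_id: "int | None",
    n: int,
    master_seed: int,
    cfg: "DynamicsConfig | None" = None,
    *,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
    batch_size: int = 4096,
) -> SearchResult:
    """Sample ``n`` phenotypes, run one trial each, count successes per target.

    ``target_id`` selects the headline ratio; counts for both targets are
    always recorded (a trial ends at its first target entry, so each success
    is attributed to the target reached).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arena = make_arena(arena_kind)
    condition = Condition(condition)
    if condition is Condition.INTENTIONAL:
        raise ValueError("use intentional_search for the intentional condition")
    cfg = cfg or DynamicsConfig()
    starts = _start_locations(arena)

    successes = {"target1": 0, "target2": 0, "any": 0}
    hits: list[dict] = []
    n_err = 0
    for batch in _batched_indices(n, batch_size):
        b = len(batch)
        weights = np.empty((b, condition.n_inputs, 32))
        sx = np.empty(b, dtype=np.int64)
        sy = np.empty(b, dtype=np.int64)
        for j, k in enumerate(batch):
            weights[j], sx[j], sy[j] = _draw_sample(master_seed, k, condition, starts)
        res = simulate_batch(
            arena, condition, weights, sx, sy, cfg,
            arch=arch, theta_act=theta_act,
        )
        n_err += int(res.error.sum())
        for j in np.flatnonzero(res.reached):
            tid = int(res.reached[j])
            successes[f"target{tid}"] += 1
            successes["any"] += 1
            hits.append(
                {
                    "index": int(batch[0] + j),
                    "target": tid,
                    "time_s": float(res.time_to_target[j]),
                    "start": [int(sx[j]), int(sy[j])],
                }
            )
    return SearchResult(
        arena_kind=ArenaKind(arena_kind).value,
        condition=condition.value,
        target_id=target_id,
        n=n,
        master_seed=master_seed,
        successes=successes,
        hits=hits,
        n_errors=n_err,
    )


def intentional_search(
    arena_kind: "ArenaKind | str",
    n: int,
    master_seed: int,
    cfg: "DynamicsConfig | None" = None,
    *,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
    budget: float = INTENTIONAL_BUDGET_S,
    batch_size: int = 4096,
) -> SearchResult:
    """Monte-Carlo search under the intentional condition.

    A phenotype succeeds only if its agent reaches target 1 while bias 1 is
    active and then target 2 under bias 2, within the total time budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arena = make_arena(arena_kind)
    condition = Condition.INTENTIONAL
    cfg = cfg or DynamicsConfig()
    starts = _start_locations(arena)

    successes = {"sequence": 0, "target1_phase": 0}
    hits: list[dict] = []
    n_err = 0
    for batch in _batched_indices(n, batch_size):
        b = len(batch)
        weights = np.empty((b, condition.n_inputs, 32))
        sx = np.empty(b, dtype=np.int64)
        sy = np.empty(b, dtype=np.int64)
        for j, k in enumerate(batch):
            weights[j], sx[j], sy[j] = _draw_sample(master_seed, k, condition, starts)
        res = simulate_batch(
            arena, condition, weights, sx, sy, cfg,
            arch=arch, theta_act=theta_act, duration=budget,
        )
        n_err += int(res.error.sum())
        successes["target1_phase"] += int((res.reached >= 1).sum())
        for j in np.flatnonzero(res.reached == 2):
            successes["sequence"] += 1
            hits.append(
                {
                    "index": int(batch[0] + j),
                    "time_target1_s": float(res.time_to_target1[j]),
                    "time_total_s": float(res.time_to_target[j]),
                    "start": [int(sx[j]), int(sy[j])],
                }
            )
    return SearchResult(
        arena_kind=ArenaKind(arena_kind).value,
        condition=condition.value,
        target_id=None,
        n=n,
        master_seed=master_seed,
        successes=successes,
        hits=hits,
        n_errors=n_err,
    )


# --------------------------------------------------------------------------
# Successful-phenotype collection and manipulation comparisons


def collect_successful_phenotypes(
    arena_kind: "ArenaKind | str",
    condition: "Condition | str",
    n_needed: int,
    master_seed: int,
    cfg: "DynamicsConfig | None" = None,
    *,
    max_samples: int = 200_000,
    batch_size: int = 4096,
) -> list[tuple[Phenotype, Location]]:
    """Search until ``n_needed`` phenotypes solving either target are found.

    Returns (phenotype, start location) pairs; the start is the one under
    which the phenotype succeeded, reused identically across comparison arms.
    """
    arena = make_arena(arena_kind)
    condition = Condition(condition)
    cfg = cfg or DynamicsConfig()
    starts = _start_locations(arena)
    found: list[tuple[Phenotype, Location]] = []
    for batch in _batched_indices(max_samples, batch_size):
        b = len(batch)
        weights = np.empty((b, condition.n_inputs, 32))
        sx = np.empty(b, dtype=np.int64)
        sy = np.empty(b, dtype=np.int64)
        for j, k in enumerate(batch):
            weights[j], sx[j], sy[j] = _draw_sample(master_seed, k, condition, starts)
        res = simulate_batch(arena, condition, weights, sx, sy, cfg)
        for j in np.flatnonzero(res.reached):
            ph = Phenotype(
                condition=condition,
                weights=weights[j],
                seed=(master_seed, int(batch[0] + j)),
            )
            found.append((ph, Location(int(sx[j]), int(sy[j]))))
            if len(found) >= n_needed:
                return found
    raise RuntimeError(
        f"found only {len(found)}/{n_needed} successful phenotypes in {max_samples} samples"
    )


@dataclass
class LesionReport:
    """Paired control-vs-manipulation comparison over successful phenotypes."""

    manipulation_value: float
    manipulation_scope: str
    manipulation_layer: "int | None"
    n_phenotypes: int
    n_paired: int
    n_manipulated_failures: int
    control_times: list
    manipulated_times: list
    mean_control: "float | None"
    sd_control: "float | None"
    mean_manipulated: "float | None"
    sd_manipulated: "float | None"
    t_statistic: "float | None"
    df: "int | None"
    p_value: "float | None"
    direction: "str | None"  # "manipulated_slower" / "manipulated_faster" / "no_change"

    def to_dict(self) -> dict:
        return asdict(self)


def lesion_comparison(
    phenotype_starts: Sequence[tuple[Phenotype, Location]],
    manipulation: tuple,
    arena: Arena,
    cfg: "DynamicsConfig | None" = None,
    *,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
) -> LesionReport:
    """Rerun each phenotype from its own start under control (b = 0) and
    manipulated EB biases; paired two-tailed t-test on times-to-target.

    ``manipulation`` is ``(value, scope)`` or ``(value, scope, layer)`` with
    scope "all" or "layer".  Phenotypes that fail under manipulation cannot
    contribute a paired time and are excluded pairwise (their count is
    reported); with fewer than two pairs the t-statistic is undefined and
    reported as None.
    """
    if len(phenotype_starts) < 2:
        raise ValueError("need at least two control-successful phenotypes")
    value, scope, *rest = manipulation
    layer = rest[0] if rest else None
    cfg = cfg or DynamicsConfig()
    condition = phenotype_starts[0][0].condition
    weights = np.stack([ph.input_matrix() for ph, _ in phenotype_starts])
    sx = np.array([loc.x for _, loc in phenotype_starts], dtype=np.int64)
    sy = np.array([loc.y for _, loc in phenotype_starts], dtype=np.int64)

    bias = manipulation_bias(value, scope, layer)
    res_ctrl = simulate_batch(arena, condition, weights, sx, sy, cfg,
                              arch=arch, theta_act=theta_act)
    res_manip = simulate_batch(arena, condition, weights, sx, sy, cfg,
                               arch=arch, theta_act=theta_act, bias=bias)

    ctrl_t = res_ctrl.time_to_target
    manip_t = res_manip.time_to_target
    paired = ~np.isnan(ctrl_t) & ~np.isnan(manip_t)
    n_manip_fail = int((~np.isnan(ctrl_t) & np.isnan(manip_t)).sum())

    c, m = ctrl_t[paired], manip_t[paired]
    if paired.sum() >= 2:
        t_res = stats.ttest_rel(c, m)
        diff = float(np.mean(m - c))
        if np.isclose(diff, 0.0):
            direction = "no_change"
        else:
            direction = "manipulated_slower" if diff > 0 else "manipulated_faster"
        report_stats = dict(
            mean_control=float(np.mean(c)),
            sd_control=float(np.std(c, ddof=1)),
            mean_manipulated=float(np.mean(m)),
            sd_manipulated=float(np.std(m, ddof=1)),
            t_statistic=float(t_res.statistic),
            df=int(paired.sum() - 1),
            p_value=float(t_res.pvalue),
            direction=direction,
        )
    else:
        report_stats = dict(
            mean_control=float(np.mean(c)) if c.size else None,
            sd_control=None,
            mean_manipulated=float(np.mean(m)) if m.size else None,
            sd_manipulated=None,
            t_statistic=None,
            df=None,
            p_value=None,
            direction=None,
        )
    return LesionReport(
        manipulation_value=value,
        manipulation_scope=scope,
        manipulation_layer=layer,
        n_phenotypes=len(phenotype_starts),
        n_paired=int(paired.sum()),
        n_manipulated_failures=n_manip_fail,
        control_times=[None if np.isnan(v) else float(v) for v in ctrl_t],
        manipulated_times=[None if np.isnan(v) else float(v) for v in manip_t],
        **report_stats,
    )


def outcome_frequencies(
    phenotype_starts: Sequence[tuple[Phenotype, Location]],
    arena: Arena,
    cfg: "DynamicsConfig | None" = None,
    *,
    bias: "np.ndarray | None" = None,
    arch: ArchConfig = DEFAULT_ARCH,
    theta_act: float = DEFAULT_THETA_ACT,
    duration: "float | None" = None,
) -> dict[str, float]:
    """Fraction of decision ticks per motor outcome over a phenotype set.

    Used to characterize the selection / conflict / freeze regimes under EB
    bias manipulations.
    """
    cfg = cfg or DynamicsConfig()
    condition = phenotype_starts[0][0].condition
    weights = np.stack([ph.input_matrix() for ph, _ in phenotype_starts])
    sx = np.array([loc.x for _, loc in phenotype_starts], dtype=np.int64)
    sy = np.array([loc.y for _, loc in phenotype_starts], dtype=np.int64)
    res = simulate_batch(arena, condition, weights, sx, sy, cfg,
                         arch=arch, theta_act=theta_act, bias=bias,
                         duration=duration, record=True, prune=False)
    out = res.trace["outcome"]
    total = out.size
    return {
        "none": float((out == OUTCOME_NONE).sum() / total),
        "selected": float((out == OUTCOME_SELECTED).sum() / total),
        "conflict": float((out == OUTCOME_CONFLICT).sum() / total),
    }
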