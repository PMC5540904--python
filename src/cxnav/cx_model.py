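"""Leaky-integrator rate model of the ellipsoid body (EB) and lateral
accessory lobes (LAL).

Units
-----
The EB comprises 2 hemispheres x 8 wedges x 3 ring-neuron layers = 48 units;
the LAL comprises 2 hemispheres x 8 premotor modules = 16 units.  Unit ``j``
obeys the mean-field dynamics

    tau_g * du_j/dt = -u_j + b_j + sum_i w_ji y_i,      y_j = [tanh(u_j)]+

where ``y`` is the rectified-saturating activation (bounded in [0, 1)),
``b_j`` a basal bias (0 everywhere except under deactivation/overactivation
manipulations of the EB) and the sum runs over sensory inputs and the fixed
recurrent circuitry.

Fixed circuitry
---------------
* symmetric lateral inhibition between EB units of different wedges within a
  hemisphere, across all layer pairs (transient winner-take-all competition);
* off-center inhibitory gating from every EB unit of wedge ``i`` to every
  LAL module ``j != i`` of both hemispheres, so a winning wedge disinhibits
  only its matched premotor module;
* excitatory feedback from LAL module ``i`` to the three EB layers of wedge
  ``i`` in the same hemisphere (efference copy of the selected command).

Free parameters
---------------
The input->EB and input->LAL weights are the *behavioral phenotype*: sampled
i.i.d. uniform on [-1, 1] and shared between hemispheres (mirror-symmetric)
by default.
"""

from __future__ import annotations

import ast
import io
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .sensory_encoding import Condition, INPUT_LABELS

N_HEMI = 2
N_WEDGES = 8
N_LAYERS = 3
N_EB = N_HEMI * N_WEDGES * N_LAYERS  # 48
N_LAL = N_HEMI * N_WEDGES  # 16
N_UNITS = N_EB + N_LAL  # 64


class NumericsError(RuntimeError):
    """Raised when the integrated state stops being finite."""


def eb_index(hemi: int, wedge: int, layer: int) -> int:
    """Global unit index of an EB unit (hemi 0=left, 1=right)."""
    return hemi * N_WEDGES * N_LAYERS + wedge * N_LAYERS + layer

def lal_index(hemi: int, module: int) -> int:
    """Global unit index of a LAL module."""
    return N_EB + hemi * N_WEDGES + module


def eb_layer_indices(layer: int) -> list[int]:
    """The 16 EB units (both hemispheres, all wedges) of one ring layer."""
    if not 0 <= layer < N_LAYERS:
        raise ValueError(f"layer out of range: {layer}")
    return [eb_index(h, w, layer) for h in range(N_HEMI) for w in range(N_WEDGES)]


UNIT_LABELS = tuple(
    f"eb:{'LR'[h]}:w{w}:l{l}"
    for h in range(N_HEMI)
    for w in range(N_WEDGES)
    for l in range(N_LAYERS)
) + tuple(f"lal:{'LR'[h]}:m{m}" for h in range(N_HEMI) for m in range(N_WEDGES))

#: labels of the hemisphere-shared phenotype weight columns (24 EB + 8 LAL)
SHARED_UNIT_LABELS = tuple(
    f"eb:w{w}:l{l}" for w in range(N_WEDGES) for l in range(N_LAYERS)
) + tuple(f"lal:m{m}" for m in range(N_WEDGES))
N_SHARED = len(SHARED_UNIT_LABELS)  # 32


@dataclass(frozen=True)
class ArchConfig:
    """Fixed architectural weights (unspecified biologically; config-exposed).

    ``lateral_inhibition`` is the weight of one between-wedge EB unit pair.
    Its default is the strongest value at which the competition stays
    *transient*: the three regimes (clean selection under control, conflict
    under deactivation, freeze under overactivation) all hold and the winner
    still flips when the two competing inputs are swapped.  Per-pair values
    near -1.0 lock in the first winner permanently (a challenger would have
    to overcome ~2 units of inhibition from the incumbent's three layers),
    while values much weaker leave so many wedges active that the off-center
    gating silences the whole LAL and nothing is ever selected.
    """

    lateral_inhibition: float = -0.3
    eb_lal_gating: float = -0.2
    lal_eb_feedback: float = 0.2
    hemisphere_shared: bool = True


DEFAULT_ARCH = ArchConfig()


@dataclass(frozen=True)
class DynamicsConfig:
    """Integration constants, in seconds."""

    tau_g: float = 0.1
    dt: float = 0.01
    decision_interval: float = 0.1
    trial_duration: float = 30.0
    integrator: str = "exponential"  # "exponential" (exact decay) or "euler"

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.tau_g:
            raise ValueError("require 0 < dt <= tau_g")
        if abs(self.steps_per_decision * self.dt - self.decision_interval) > 1e-9:
            raise ValueError("decision_interval must be an integer multiple of dt")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.integrator not in ("exponential", "euler"):
            raise ValueError(f"unknown integrator: {self.integrator!r}")

    @property
    def steps_per_decision(self) -> int:
        return int(round(self.decision_interval / self.dt))

    def n_decisions(self, duration: "float | None" = None) -> int:
        return int(round((duration or self.trial_duration) / self.decision_interval))


@dataclass(frozen=True)
class ConnectionSet:
    """Fixed recurrent weights plus (optionally) the phenotype input weights.

    All matrices are target x source.  ``recurrent`` is the assembled 64x64
    matrix over [EB, LAL] unit ordering.
    """

    arch: ArchConfig
    w_eb_lateral: np.ndarray  # (48, 48)
    w_eb_lal: np.ndarray  # (16, 48)
    w_lal_eb: np.ndarray  # (48, 16)
    w_input_eb: "np.ndarray | None" = None  # (n_inputs, 48), column = target unit
    w_input_lal: "np.ndarray | None" = None  # (n_inputs, 16)

    @property
    def recurrent(self) -> np.ndarray:
        top = np.hstack([self.w_eb_lateral, self.w_lal_eb])
        bottom = np.hstack([self.w_eb_lal, np.zeros((N_LAL, N_LAL))])
        return np.vstack([top, bottom])

    def input_matrix(self) -> np.ndarray:
        if self.w_input_eb is None or self.w_input_lal is None:
            raise ValueError("input weights not populated; call with_phenotype first")
        return np.hstack([self.w_input_eb, self.w_input_lal])

    def with_phenotype(self, phenotype: "Phenotype") -> "ConnectionSet":
        full = phenotype.input_matrix()
        return replace(self, w_input_eb=full[:, :N_EB], w_input_lal=full[:, N_EB:])


def build_cx(arch: ArchConfig = DEFAULT_ARCH) -> ConnectionSet:
    """Assemble the fixed EB/LAL circuitry; phenotype slots stay empty."""
    lat = np.zeros((N_EB, N_EB))
    for h in range(N_HEMI):
        for wt in range(N_WEDGES):
            for lt in range(N_LAYERS):
                t = eb_index(h, wt, lt)
                for ws in range(N_WEDGES):
                    if ws == wt:
                        continue
                    for ls in range(N_LAYERS):
                        lat[t, eb_index(h, ws, ls)] = arch.lateral_inhibition
    gate = np.zeros((N_LAL, N_EB))
    for ht in range(N_HEMI):
        for m in range(N_WEDGES):
            t = ht * N_WEDGES + m
            for hs in range(N_HEMI):
                for w in range(N_WEDGES):
                    if w == m:
                        continue
                    for l in range(N_LAYERS):
                        gate[t, eb_index(hs, w, l)] = arch.eb_lal_gating
    fb = np.zeros((N_EB, N_LAL))
    for h in range(N_HEMI):
        for w in range(N_WEDGES):
            for l in range(N_LAYERS):
                fb[eb_index(h, w, l), h * N_WEDGES + w] = arch.lal_eb_feedback
    return ConnectionSet(arch=arch, w_eb_lateral=lat, w_eb_lal=gate, w_lal_eb=fb)


@dataclass(frozen=True)
class Phenotype:
    """One sampled configuration of input->EB/LAL connection weights."""

    condition: Condition
    weights: np.ndarray  # (n_inputs, 32) hemisphere-shared, or (n_inputs, 64)
    seed: "int | tuple | None" = None
    hemisphere_shared: bool = True

    def __post_init__(self) -> None:
        n_cols = N_SHARED if self.hemisphere_shared else N_UNITS
        if self.weights.shape != (self.condition.n_inputs, n_cols):
            raise ValueError(
                f"phenotype weights must have shape ({self.condition.n_inputs}, {n_cols})"
            )

    @property
    def n_inputs(self) -> int:
        return self.condition.n_inputs

    def input_matrix(self) -> np.ndarray:
        """Full (n_inputs, 64) matrix, mirroring shared weights across hemispheres."""
        if not self.hemisphere_shared:
            return self.weights
        eb_half = self.weights[:, : N_WEDGES * N_LAYERS]
        lal_half = self.weights[:, N_WEDGES * N_LAYERS :]
        return np.concatenate([eb_half, eb_half, lal_half, lal_half], axis=1)


def sample_phenotype(
    seed: "int | tuple | np.random.SeedSequence",
    condition: Condition = Condition.COMBINED,
    hemisphere_shared: bool = True,
) -> Phenotype:
    """Draw every free weight i.i.d. uniform on [-1, 1]; deterministic per seed."""
    condition = Condition(condition)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_cols = N_SHARED if hemisphere_shared else N_UNITS
    weights = rng.uniform(-1.0, 1.0, size=(condition.n_inputs, n_cols))
    seed_record = seed if not isinstance(seed, np.random.SeedSequence) else tuple(ss.entropy if isinstance(ss.entropy, (list, tuple)) else [ss.entropy])
    return Phenotype(condition=condition, weights=weights, seed=seed_record,
                     hemisphere_shared=hemisphere_shared)


@dataclass(frozen=True)
class UnitPool:
    """Activation potentials ``u``, activations ``y`` and biases ``b``."""

    u: np.ndarray
    y: np.ndarray
    b: np.ndarray

    @classmethod
    def zeros(cls) -> "UnitPool":
        z = np.zeros(N_UNITS)
        return cls(u=z.copy(), y=z.copy(), b=z.copy())


def transfer(u):
    """Positive-saturation transfer [tanh(u)]+, bounded in [0, 1)."""
    return np.maximum(np.tanh(u), 0.0)


def step_dynamics(
    pool: UnitPool,
    conn: ConnectionSet,
    sensory: np.ndarray,
    cfg: DynamicsConfig = DynamicsConfig(),
) -> UnitPool:
    """One integration step of the leaky-integrator network.

    ``sensory`` is the assembled input vector; its weighted projection enters
    the same summed input as the recurrent terms.  The default integrator is
    exponential Euler (exact for the decay term, first-order in the recurrent
    coupling); plain forward Euler is available via the config.
    """
    net = conn.recurrent @ pool.y + conn.input_matrix().T @ sensory + pool.b
    if cfg.integrator == "euler":
        u = pool.u + (cfg.dt / cfg.tau_g) * (net - pool.u)
    else:
        alpha = np.exp(-cfg.dt / cfg.tau_g)
        u = net + (pool.u - net) * alpha
    if not np.all(np.isfinite(u)):
        raise NumericsError("non-finite activation potential encountered")
    return UnitPool(u=u, y=transfer(u), b=pool.b)


def manipulation_bias(value: float, scope: str = "all", layer: "int | None" = None) -> np.ndarray:
    """Bias vector implementing an EB deactivation (< -0.5) or overactivation
    (> 0.5) manipulation; LAL biases stay 0."""
    b = np.zeros(N_UNITS)
    if scope == "all":
        b[:N_EB] = value
    elif scope == "layer":
        if layer is None:
            raise ValueError("scope='layer' requires a layer index")
        b[eb_layer_indices(layer)] = value
    else:
        raise ValueError(f"unknown manipulation scope: {scope!r}")
    return b


def apply_manipulation(
    pool: UnitPool, value: float, scope: str = "all", layer: "int | None" = None
) -> UnitPool:
    """Set ``b_j`` on the selected EB units, leaving all other biases alone."""
    b = pool.b.copy()
    mask = manipulation_bias(1.0, scope, layer) != 0
    b[mask] = value
    return replace(pool, b=b)


# --------------------------------------------------------------------------
# Phenotype file format: flat CSV of named weights plus seed metadata.


def phenotype_to_csv(phenotype: Phenotype) -> str:
    cols = SHARED_UNIT_LABELS if phenotype.hemisphere_shared else UNIT_LABELS
    inputs = INPUT_LABELS[: phenotype.n_inputs]
    buf = io.StringIO()
    buf.write("# cxnav phenotype\n")
    buf.write(f"# condition: {phenotype.condition.value}\n")
    buf.write(f"# hemisphere_shared: {phenotype.hemisphere_shared}\n")
    buf.write(f"# seed: {phenotype.seed!r}\n")
    buf.write("input,unit,weight\n")
    for i, ilab in enumerate(inputs):
        for j, ulab in enumerate(cols):
            buf.write(f"{ilab},{ulab},{phenotype.weights[i, j]:.17g}\n")
    return buf.getvalue()


def phenotype_from_csv(text: str) -> Phenotype:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#") and ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    condition = Condition(meta["condition"])
    shared = meta.get("hemisphere_shared", "True") == "True"
    seed_repr = meta.get("seed", "None")
    try:
        seed = ast.literal_eval(seed_repr)
    except (ValueError, SyntaxError):
        seed = seed_repr
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    cols = SHARED_UNIT_LABELS if shared else UNIT_LABELS
    inputs = INPUT_LABELS[: condition.n_inputs]
    pivot = df.set_index(["input", "unit"])["weight"]
    weights = np.array([[pivot[(i, u)] for u in cols] for i in inputs])
    return Phenotype(condition=condition, weights=weights, seed=seed, hemisphere_shared=shared)


def save_phenotype(phenotype: Phenotype, path) -> None:
    with open(path, "w") as fh:
        fh.write(phenotype_to_csv(phenotype))


def load_phenotype(path) -> Phenotype:
    with open(path) as fh:
        return phenotype_from_csv(fh.read())
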