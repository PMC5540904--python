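# Methods

## The model

`cxnav` simulates spatial navigation driven by the insect central complex at
the level of mean-field rate units.  Each unit `j` — a pool of neurons, not
a single cell — carries an activation potential `u_j` with leaky-integrator
dynamics

    τ_g u̇_j = −u_j + b_j + Σ_i w_ji y_i,      y_j = [tanh(u_j)]⁺.

The architecture follows the known macro-connectivity of the ellipsoid body
(EB) and lateral accessory lobes (LAL):

* **EB**: 2 hemispheres × 8 wedges × 3 tangential ring-neuron layers = 48
  units.  All sensory inputs project onto all EB units (columnar, "all
  segments of sensory space"), and ring-neuron lateral inhibition couples
  every pair of units belonging to *different* wedges of the same
  hemisphere, across all layer pairs.  There is no intra-wedge coupling:
  wedge units interact only through shared inputs and shared targets.
* **EB → LAL off-center gating**: each EB unit inhibits every LAL module
  whose index differs from its own wedge, in both hemispheres.  A winning
  wedge therefore disinhibits exactly its matched premotor module — the
  disinhibition motif of selection circuits.
* **LAL → EB feedback**: each LAL module excites the three layers of its
  matched wedge on its own side, an efference copy of the selected command.
* **LAL**: 2 × 8 modules.  Modules 1–3 (per hemisphere) map to *move
  forward*, *turn left*, *turn right*; modules 4–8 drive actions with no
  spatial consequence (grooming, feeding, standing still, …) that
  nevertheless compete for selection.

The free parameters are the input weights onto EB and LAL.  They are shared
between hemispheres (mirror-symmetric phenotype), halving the search
dimension; a config switch (`hemisphere_shared=False`) enables independent
hemispheres.  One sampled configuration — uniform i.i.d. on [−1, 1] — is a
*behavioral phenotype*: a fixed stimulus-response policy, standing in for
the outcome of a (not modeled) reinforcement-learning process.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `tau_g` | 0.1 | s | integrator time constant; selection settles within one decision interval |
| `dt` | 0.01 | s | integration step |
| `decision_interval` | 0.1 | s | motor readout cadence; one location or 90° per selected tick |
| `trial_duration` | 30 | s | per-trial budget (60 s total for the two-goal intentional task) |
| `theta_act` | 0.5 | – | motor threshold on hemisphere-averaged LAL activity |
| `lateral_inhibition` | −0.3 | – | EB unit-pair weight, between wedges within a hemisphere |
| `eb_lal_gating` | −0.2 | – | per-EB-unit off-center inhibition of non-matching LAL modules |
| `lal_eb_feedback` | +0.2 | – | wedge-matched LAL→EB excitation |

The three fixed circuit weights are not identifiable from published
anatomy; they were chosen — once, on qualitative grounds only — as the
configuration closest to unit scale that simultaneously exhibits every
regime the circuit is supposed to show:

1. **Transient winner-take-all**: with constant drives 0.9 and 0.6 to two
   wedges, the stronger wedge settles above the motor threshold and the
   weaker below it; *swapping* the drives flips the winner.  Per-pair
   inhibition near −1.0 fails this: the incumbent's three layers deliver
   ~2 units of inhibition and the selection locks in permanently.
2. **Selection at all**: per-pair inhibition much below ~0.1 leaves several
   wedges active at once, and the summed off-center gating then silences
   the entire LAL; nothing is ever selected.
3. **The three manipulation regimes** (see below): clean selection under
   control, conflict flooding under EB deactivation, post-first-selection
   freezing under strong overactivation.
4. **Qualitative search structure**: random-phenotype successes occur in
   the combined-input open arena and not under single-source conditions.

(−0.3, −0.2, +0.2) is the strongest-inhibition configuration satisfying all
four; all three weights are exposed in the configuration.

## Integration

The integrator is exponential Euler: `u ← I + (u − I)·e^(−dt/τ)` with the
summed input `I` held over the step.  It is *exact* for the leak — a unit
under constant net input follows the continuous solution to machine
precision at any step size — and first-order in the recurrent coupling,
with the same fixed points as the continuous system.  Plain forward Euler
is available (`integrator="euler"`) but its decay mode alone leaves a
residual-transient error of ≈1.6×10⁻³ per unit of amplitude at t = 5τ with
dt = 0.01, which is why it is not the default.  Trajectories through the
winner-take-all competition itself are resolution-sensitive near ties
(discretization can tip a near-symmetric race); fixed-point locations and
winner identities away from ties are step-size robust, and the oracle tests
compare against 100×-finer integration in the constant-net-input setting
where the comparison is well-posed.

## Simulated environment and sensory code

Arenas are 40 × 40 grids of unit locations (1-based, x west→east, y
south→north), partitioned into sixteen 10 × 10 sectors numbered row-major
from the southwest.  The start region is sector 1; targets 1 and 2 are
sectors 14 and 16; four landmarks occupy the corner sectors (default 1 = SW,
2 = SE, 3 = NE, 4 = NW — the published assignment is ambiguous, so it is
configurable).  The simple maze adds a wall at y = 21 pierced by a
one-sector passage (x 21–30); the complex maze (shipped as an ASCII
fixture, validated at load time) adds three staggered walls so that exactly
five well-timed turns are needed to reach either target — a parity argument
over the passage columns gives the lower bound and breadth-first search
over (location, heading) states confirms equality.  Blocked forward
commands are ignored silently but still consume their decision tick.

Sensory input is egocentric and sector-grained: a landmark's identity unit
reads 1.0 in the agent's own sector, 0.5 anywhere else in the forward
180°-arc visual field (realized on the 4 × 4 sector grid as "not strictly
behind"), and six binary angular units pool landmark bearings (left,
front-left, front, front-right, right, same sector) without identity.
Internal walls do not occlude landmarks.  Body orientation is a one-hot
N/E/S/W vector.  Input therefore depends only on (sector, heading, bias
phase), which the batch engine exploits via a 16 × 4 lookup table; the
tests verify within-sector invariance and rotation equivariance
exhaustively.  Excluded source blocks (vision-only / orientation-only
conditions) are zeroed in place so phenotype dimensionality is constant.

## Experiments

* **Monte-Carlo search**: one trial per phenotype from a uniformly drawn
  start location, initial heading East, initial potentials zero.
  Per-sample randomness comes from `SeedSequence((master_seed, index))`, so
  results are independent of batch partitioning.  Desk-scale defaults are
  10⁴–10⁵ samples per condition (the published searches used 2×10⁶ per
  condition, which is cluster-scale); ratios are reported per 10⁶.
* **Trial termination**: a trial ends at its first entry into either
  target; the success is attributed to the target actually reached.
* **Manipulations**: deactivation sets `b_j < −0.5` and overactivation
  `b_j > 0.5` on all EB units (or one ring layer).  The paired comparison
  reruns each control-successful phenotype from its own start location
  under both arms; manipulated runs that fail are excluded pairwise from
  the two-tailed paired t-test and reported as a count.
* **Intentional navigation**: two interoceptive bias units (e.g. hunger /
  thirst) are appended to the input; bias 1 is active from t = 0 until
  target 1 is entered, then bias 2 until target 2 or the 60 s budget ends.
  Success requires both targets in order.
* **Early termination (exact)**: a trial whose agent has not moved for a
  full decision tick and whose potentials changed by less than 10⁻¹⁰ is at
  a fixed point under static input and can never act again; it is recorded
  as a failure immediately.  Pruned and unpruned runs are verified to
  produce identical outcomes.

## What the synthetic world does and does not capture

The generator *is* the study system: discrete space, four headings,
sector-grained vision, noiseless dynamics and deterministic trials.  It
does not emulate continuous kinematics, graded landmark distance, sensory
or neural noise, occlusion, or learning of the weights — so passing tests
demonstrate properties of the selection circuit and of the search
procedure, not predictions about real insects or about noisy continuous
environments.

## Known limitations

* **Absolute success ratios.**  The published description pins neither the
  sampling distribution of the weights, the motor threshold, the
  integration constants, nor the strengths of the fixed circuitry, and the
  Monte-Carlo success rate is extremely sensitive to all of them.  Under
  this package's canonical parameterization the qualitative comparisons
  reproduce (combined-input successes exist and dominate single-source
  conditions, which are zero or near-zero; open arena ≫ mazes; one-layer
  overactivation slows navigation, with control times ≈ 3.6–4.3 s that are
  close to the published control mean), but the absolute rates are of order
  10² per 10⁶ rather than the published 6.9×10³ per 10⁶, and the rare
  sequential-goal solutions (printed: 90 per 10⁶) are not observed at 10⁵
  desk-scale samples.  Matching the printed rates would require jointly
  recalibrating threshold and input scale against those same rates, which
  this package deliberately does not do.
* **Vision-only leakage.**  Because the visual field rotates with the body,
  visual input carries implicit heading information; occasional vision-only
  successes (order 10⁻⁴) can occur, whereas the original reports exactly
  zero in 2×10⁶.
* The LAL is modeled without internal lateral connectivity; EB layers are
  symmetric (no layer hierarchy); dopamine-dependent learning, the
  protocerebral bridge, fan-shaped body and noduli are out of scope.
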