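# cxnav

Simulation of insect central-complex (CX) mediated spatial navigation.  A
bio-constrained leaky-integrator rate model of the ellipsoid body (EB) and
lateral accessory lobes (LAL) integrates egocentric visual and
body-orientation inputs, performs transient winner-take-all action
selection, and steers a simulated insect through discrete 2-D arenas of
increasing complexity.  Monte-Carlo searches over the free input weights
("behavioral phenotypes") quantify how often random stimulus-response
wirings solve each navigation task, and bias manipulations of the EB
reproduce characteristic selection pathologies (motor conflict, behavioral
freezing).

The package is aimed at computational neuroscientists studying action
selection and sensorimotor integration in the insect central complex, and at
anyone who needs a compact, fully reproducible test bed for
disinhibition-style selection circuits coupled to a closed sensorimotor
loop.

## Model

Each of the 48 EB units (2 hemispheres × 8 wedges × 3 ring-neuron layers)
and 16 LAL units (2 × 8 premotor modules) is a mean-field pool obeying

    τ_g u̇_j = −u_j + b_j + Σ_i w_ji y_i,      y_j = [tanh(u_j)]⁺

with τ_g = 0.1 s, basal bias b_j = 0 (nonzero only under
deactivation/overactivation experiments), and activations bounded in
[0, 1).  The fixed circuitry comprises symmetric lateral inhibition between
EB wedges within a hemisphere (transient winner-take-all), off-center
inhibitory gating from each EB wedge onto every non-matching LAL module
(disinhibition selects exactly one premotor channel), and wedge-matched
excitatory feedback from the LAL back to the EB.  The free parameters — the
weights from the 14-dimensional sensory vector (4 body-orientation, 4
landmark-identity, 6 angular-position units; plus 2 interoceptive biases in
the intentional condition) onto EB and LAL — constitute a behavioral
phenotype, sampled i.i.d. uniform on [−1, 1].

Every 0.1 s the mean LAL module activities are read out: a single
supra-threshold drive (θ_act = 0.5) executes its action (modules 1–3 map to
*forward*, *turn left*, *turn right*; 5 further modules are
spatially-neutral actions), multiple supra-threshold drives are a motor
conflict (arrest), none leaves the agent motionless.  Agents navigate
40 × 40 arenas (open, simple maze, complex maze) from a 10 × 10 start
region toward two 10 × 10 target areas within 30 s of simulated time.

## Worked example

A hand-wired phenotype — *forward* driven by landmark 1 in the current
sector or by heading North, *turn left* driven by heading East but vetoed
while landmark 1 is still in view of the start sector — solves the open
arena:

```python
import numpy as np
from cxnav import Condition, Location, Phenotype, make_arena, run_trial

W = np.zeros((14, 32))
for l in range(3):                    # EB wedge 0 = forward, wedge 1 = turn left
    W[0, 0 + l] = 1.0; W[4, 0 + l] = 1.0
    W[1, 3 + l] = 1.0; W[4, 3 + l] = -1.0
W[0, 24] = 1.0; W[4, 24] = 1.0        # LAL module 0 (forward)
W[1, 25] = 1.0; W[4, 25] = -1.0       # LAL module 1 (turn left)
ph = Phenotype(condition=Condition.COMBINED, weights=W, seed="handcrafted")

res = run_trial(make_arena("open"), ph, start=Location(5, 5))
print(f"reached target: {res.reached_target}  time: {res.time_to_target} s")
print(res.trajectory.iloc[[0, 5, 9, 11, -1]].to_string(index=False))
```

prints

```
reached target: 1  time: 3.6 s
 tick  time_s  x  y heading  action  outcome
    0     0.1  6  5       E FORWARD selected
    5     0.6 11  5       E FORWARD selected
    9     1.0 11  5       N             none
   11     1.2 11  7       N FORWARD selected
   35     3.6 11 31       N FORWARD selected
```

The agent runs east out of the start sector, turns left once in sector
column 2 (the `none` ticks are the selection hand-over), then runs north
until it enters target 1 (sector 14) after 3.6 s.

The command-line interface exposes the same operations:

```bash
cxnav validate-arena           # min-turn counts: 1 / 2 / 5 per arena
cxnav search --arena open --condition combined --n 20000 --seed 1 --out search.json
cxnav intentional --arena open --n 100000 --seed 1 --out intentional.json
cxnav lesion --arena open --n-phenotypes 20 --b-value 0.5 --scope layer --seed 1 --out lesion.json
cxnav run-trial --arena open --condition combined --seed 3 --out-prefix demo
```

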