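# crnevolve

Evolving oscillatory mass-action chemical reaction networks with a
speciated genetic algorithm.

Systems biologists often want *candidate mechanisms*: small chemical
reaction networks whose dynamics reproduce a behaviour — a sustained
oscillation, or an observed time series — without committing to a single
hand-built model. `crnevolve` searches the space of mass-action networks
directly. It adapts the NEAT recipe (NeuroEvolution of Augmenting
Topologies) from neural networks to chemistry: network topology and rate
constants evolve together, deleted reactions persist as disabled genes
that can reactivate or cross over, and the population is split into
*species* of structurally similar networks so that topological innovations
get time to tune their rate constants before competing with the incumbent
best. Evolved candidates are then screened with a linear-stability test,
automatically repaired, and pruned to minimal oscillating mechanisms.

## The algorithm in brief

* **Encoding** — a network is a list of mass-action reactions over a fixed
  species set; each reaction has 1–2 reactants, 1–2 products, a rate
  constant k ≥ 0 and an active flag. Rate law: v = k·∏[reactants].
* **Mutation** — perturb one rate constant by ±20% (occasionally redraw it
  from [0.1, 50]), and/or add a random reaction or switch one off (50/50).
* **Crossover** (optional; it turns out to *hurt* on this domain) — the
  fitter parent's topology, with shared reactions' rate constants drawn
  from either parent; inactive genes reactivate with probability 0.25.
* **Speciation** — compatibility distance δ = M/N, the fraction of the
  larger network's reaction genes missing from the smaller; a threshold
  δ_t adapts each generation to hold the species count at a target
  (default 10).
* **Fitness** — simulate the ODEs (LSODA, analytic Jacobian) and score
  `max_s 1/Σ|ideal − candidate_s|` over 11 checkpoints alternating between
  two reference concentrations C1/C2 across 5.5 imposed periods; networks
  that cannot be simulated score 0 and are removed.
* **Reproduction** — fitness-proportionate offspring per species (capped
  at 10% of the population), per-species elitism and bottom-10% culling,
  random or tournament parent selection.
* **Classification** — a candidate oscillates if the Jacobian at a steady
  state has an eigenvalue with Re > 0 and Im ≠ 0 and steady-state
  concentrations are positive; flagged models get a single-deletion
  repair; pruning strips every reaction not needed for the verdict.

## Worked example

The Lotka-Volterra predator-prey system, written in the package's
encoding (prey growth `S0 -> 2 S0`, predation `S0 + S1 -> 2 S1`, predator
removal into the inert sink `S1 -> S2`):

```python
import numpy as np
from crnevolve import ClassificationConfig, classify
from crnevolve.fixtures import lotka_volterra
from crnevolve.network import write_antimony

fix = lotka_volterra(1.0, 1.0, 1.0)
res = classify(fix.network, ClassificationConfig(center_tolerance=True))
print("verdict:", res.verdict)
print("steady state:", np.round(res.steady_state, 6))
print("eigenvalues:", np.round(res.eigenvalues, 6))
```

prints

```
verdict: oscillator
steady state: [ 1.        1.       51.142919]
eigenvalues: [0.+0.j 0.+1.j 0.-1.j]
```

The prey/predator steady state lands on the closed form (k3/k2, k1/k2) =
(1, 1); the sink species S2 just accumulates and is excluded from the
stationarity condition. The eigenvalue pair ±i·√(k1·k3) = ±i is a
neutrally stable center, which the `center_tolerance` mode accepts as an
oscillator (strict mode demands a positive real part — an unstable focus).
`write_antimony(fix.network)` serialises the model as human-readable
Antimony text:

```
J0: S0 -> S0 + S0; k0*S0;
J1: S0 + S1 -> S1 + S1; k1*S0*S1;
J2: S1 -> S2; k2*S1;
```

## Command line

```
crnevolve evolve --seed 7 --out-dir run7          # one evolution trial
crnevolve batch --trials 50 --seed 1              # many trials + success rate
crnevolve classify run7/species_*_best.ant        # oscillator verdicts
crnevolve fit observed.csv --seed 3               # match a time series
```

Every trial writes its fully resolved settings as JSON; re-running with
that file reproduces the trial exactly. Batch experiments at the full
reference scale (hundreds of 800-generation trials per condition) are a
cluster workload; the defaults here are desk-sized.

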