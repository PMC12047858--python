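# Methods

`crnevolve` evolves small mass-action chemical reaction networks toward a
target behaviour — by default an imposed oscillation — with a genetic
algorithm adapted from NEAT (NeuroEvolution of Augmenting Topologies):
topology and rate constants evolve together, deactivated reactions persist
as heritable genes, and the population is partitioned into species so that
structural innovations compete only against similar networks.

## Model and encoding

A network has a fixed set of chemical species (default 3, named
`S0, S1, ...`) and a variable list of reactions. Each reaction has one or
two reactants, one or two products (uni-uni, uni-bi, bi-uni, bi-bi), a
non-negative mass-action rate constant, and an active flag. The rate law
is `v = k * prod(reactant concentrations)` with multiplicity: for
`2A -> B`, `v = k[A]^2` and A is consumed at `2v`. All species are
floating; there are no explicit boundary sources or sinks, so removal is
expressed by conversion into a species nothing consumes. Self-maps such as
`A -> 2A` are legal (autocatalytic growth needs them); a pure no-op
`A -> A` is legal but dynamically inert.

Reaction identity is the pair of reactant/product multisets — rate
constants and activity are excluded. Inserting a duplicate key adds the
new rate constant to the existing reaction (reactivating it if it was
inactive), which lets individual constants grow well past the initial
range, a feature many synthetic oscillators rely on.

Initial populations draw 5 reactions per network (duplicates merge), rate
constants uniform in [0.1, 50], and initial concentrations uniform in
[0, 10] per species (configurable; nothing in the algorithm depends on
this range).

## Genetic operators

*Rate mutation* scales one uniformly chosen active reaction's constant by
a uniform factor in ±20%, or — with probability 0.1 — redraws it uniformly
from [0.1, 50]. Constants can never become negative and have no upper
bound. *Topology mutation* adds a random reaction or deactivates a random
active one, 50/50; a network with nothing left to delete falls back to
addition. Per offspring, rate mutation fires with probability 0.6 and
topology mutation with probability 0.4 (both may fire; the draw repeats
until at least one does, since the reproduction step promises a modified
offspring). Deactivated reactions stay in the genome and may reactivate.

*Crossover* (off by default — it measurably hurts this problem domain)
passes the fitter parent's reaction list to the offspring; keys present in
both parents take their rate constant from a uniformly chosen parent, and
inherited inactive reactions reactivate with probability 0.25. A *lenient*
variant applies when parents' fitnesses are within 5% of each other:
shared keys are always inherited, unshared keys with probability 0.5.

## Speciation

The compatibility distance between two networks is `delta = M/N`, where N
is the recorded-reaction count of the larger network and M the number of
its reactions absent from the smaller one. *All reaction records count,
active or not* — the same convention NEAT uses for disabled connection
genes. This is deliberate: restricted to active reactions, delta collapses
to the two values {0, 1} whenever evolved active sets are small (one or
two reactions), the adaptive threshold saturates at 1.0, and the species
count floors far above its target. With genotypic distance the controller
behaves as intended (below). Rate constants never enter the distance.

Each generation, every network is compared against species representatives
(the best member of each species in the previous generation, ties broken
toward the older network) in stable species order; the first species with
`delta < delta_t` claims it, and a network matching none founds a new
species that is immediately available to its siblings. The threshold
adapts by a fixed step `epsilon` per generation: up if there are more
species than the target (default 10), down if fewer, clamped to [0, 1].
Defaults `delta_t(0) = 0.3`, `epsilon = 0.05`. In a default seeded run the
species count starts near one-per-network (~70-80 of 100), over/undershoots
while `delta_t` searches, enters the 10 ± 2 band by about generation 15 and
then holds it, with `delta_t` equilibrating near 0.7.

## Objective

The ideal-oscillator target imposes a period T and two reference
concentrations C1, C2, checked at the 11 half-period checkpoints
T/2, T, 3T/2, ..., 11T/2 (C1 at odd half-periods, C2 at full periods, 5.5
periods total). For each species, D_s sums the absolute checkpoint
deviations; the fitness is `max_s 1/D_s` — only the single best-matching
species counts, so the objective is invariant under species relabeling.
Deviations below 1e-9 cap the fitness at 1e9 (the reciprocal is singular
at a perfect match). Unsimulable candidates score exactly 0.0 and are
removed from the population after evaluation.

Defaults are T = 1, C1 = 10, C2 = 2. The C1/C2 spacing interacts with the
early-stop threshold (0.05): a network holding one species *constant* at
C1 scores `1/(5|C1-C2|)`, so the references must satisfy `|C1-C2| > 4` or
flat-line networks reach the stop level without oscillating. With the
defaults the constant plateau sits at 1/40 = 0.025, half the stop level.

Time-series fitting replaces the checkpoint grid with an observed table
(`time,S0,S1,...`); the deviation sums over all species and sample times
with a fixed column-to-species correspondence (no permutation matching),
with the same failure and cap rules.

## Reproduction

Species fitness is its best member's fitness. Offspring quotas follow
fitness-proportionate allocation: `round(f_s / sum_f * population)`,
clipped at 10% of the population per species, capped surplus *not*
redistributed — so the realised population size fluctuates slightly, as
intended. The cap exists to stop one species taking over; with speciation
disabled (a single global group) it does not bind. If every species scores
zero, quotas are uniform.

Per species: the top `ceil(10%)` members (one, for species of ≤ 10) are
copied unmodified; a species allocated exactly one offspring instead gives
its best network a trial mutation kept only if it improves fitness. The
bottom `floor(10%)` are culled from the parent pool. Remaining quota is
filled by drawing `p ~ U(0,1)`: `p < p_crossover` mates two parents
(uniformly, or by two-way tournament when configured) into one offspring,
`p >= 1 - p_mutation` mutates it; the config enforces
`p_crossover + p_mutation >= 1`, so every non-elite offspring is changed.
The loop stops at `max_generations` (default 800) or when the best fitness
reaches `fitness_stop` (default 0.05). A single numpy Generator seeded
from the config drives every draw, so a trial is exactly reproducible from
its settings file; batches derive per-trial seeds from one root seed.

## Simulation and numerics

Networks compile to index arrays once per evaluation; the integrator hot
path uses a plain-Python right-hand-side closure (faster than numpy fancy
indexing at 2-10 reactions) with the analytic Jacobian. Integration uses
LSODA (stiff/non-stiff switching) at rtol 1e-6, atol 1e-9, capped at
20 000 internal steps. Any failure — non-convergence, step-cap breach,
NaN, or any concentration exceeding 1e7 (finite-time blow-up, which random
autocatalytic networks produce routinely) — is reported as an unsuccessful
trajectory, never an exception. Small negative round-off concentrations
are clamped to zero.

Steady states are located by integrating to t = 50, then refining the
endpoint with a damped Newton (Powell hybrid) iteration using the analytic
Jacobian, up to 3 restarts from perturbed endpoints; acceptance requires
`||rhs||_inf < 1e-9`. The root condition applies to the *recurrent*
subsystem only: species that are never reactants of a dynamically
effective reaction (pure sinks, e.g. the removal product in a
predator-prey chain) accumulate mass without influencing anything, so
their derivatives are not required to vanish and they are reported at
their trajectory endpoint. Without this reduction no network that funnels
mass into a sink would ever have a steady state.

## Oscillator classification, repair, pruning

A network is a sustained oscillator if the Jacobian at its steady state
has an eigenvalue with positive real part and nonzero imaginary part (an
unstable focus, suggesting a limit cycle) and the steady-state
concentrations of the recurrent species are strictly positive. Passing
the eigenvalue test with a non-positive concentration *flags* the network;
finding no steady state yields *undetermined*. Strict mode requires
`Re > 1e-9`; the `center_tolerance` mode relaxes this to `Re >= -1e-6` so
neutrally stable centers — the Lotka-Volterra predator-prey system, whose
interior fixed point has purely imaginary eigenvalues ±i·sqrt(k1·k3), is
the canonical example — also classify as oscillators. Which mode a batch
used is recorded in its configuration.

Repair deactivates each active reaction in turn and returns the first
single-deletion variant that classifies as an oscillator. Pruning greedily
removes any reaction whose removal preserves the verdict until none
remains; the result always still classifies.

## Problem sizes used by the tests and the acceptance script

The reference experiments behind this algorithm run 700 independent trials
of 800-generation, 100-individual evolution per condition — a cluster-scale
workload. The packaged checks scale this to a single desk CPU and state it
here: the acceptance tests use 100-individual/40-generation runs for the
speciation-controller check and 6-trial batches of 50-individual/
60-generation runs per condition for the directional comparisons;
`scripts/acceptance.py` uses the same batch sizes plus a 150-network random
baseline and one 5-trial batch of *full-length* (100-individual,
800-generation) default-condition trials. At the shortened sizes
oscillator discovery is rare in *every* condition, so those success-rate
comparisons are directional and may compare small counts; the diversity
statistics (unique-network fraction up, best-network takeover down under
speciation) carry the robust signal there. Discovery does occur at full
trial length — successful trials typically early-stop within a few hundred
generations, and roughly a fifth of full-length default trials succeed —
which the full-length batch measures directly. Larger batches are
available through the `batch` CLI for anyone with the CPU budget.

## Known limitations

* The add/delete mutation balance interacts with the unknowable flat
  regions of the objective: populations can linger on constant-valued
  near-minimal networks for many generations before a topology innovation
  escapes. At full scale this is the expected regime (most trials spend
  hundreds of generations below the stop threshold).
* The eigenvalue criterion is a local test at a steady state; it suggests
  but does not prove a limit cycle (no Floquet/shooting analysis).
* Networks that are identical up to a permutation of species names are
  treated as distinct everywhere (distance, uniqueness, fitting).
* The synthetic time-series generator samples its own simulated
  trajectories on a uniform grid without observation noise; matching real
  experimental data would additionally face noise, sparse sampling, and
  unobserved species, none of which these tests exercise.
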