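"""The generational loop.

Each generation: evaluate fitness, sort the population into species,
adapt the speciation threshold, allocate per-species offspring in
proportion to species fitness (capped at a fraction of the next
generation, surplus not redistributed — the population size therefore
fluctuates slightly), copy elites unmodified, cull the bottom of each
species, and fill the remaining quota with offspring produced by
crossover and/or mutation.

Everything is driven by one ``numpy`` Generator seeded from the config,
so a trial is exactly reproducible from its settings file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import genetic_ops
from .fitness import OscillatorTarget, TimeSeriesTarget, oscillator_fitness, timeseries_fitness
from .genetic_ops import CrossoverConfig, MutationConfig
from .network import ReactionNetwork, random_network, write_antimony
from .speciation import (
    SpeciationState,
    SpeciesGroup,
    adapt_threshold,
    assign_species,
    diversity_metrics,
)

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "EvolutionResult",
    "allocate_offspring",
    "select_elites",
    "cull",
    "tournament_select",
    "next_generation",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 100
    max_generations: int = 800
    n_species: int = 3
    n_reactions: int = 5
    init_conc_range: tuple[float, float] = (0.0, 10.0)
    elite_fraction: float = 0.10
    cull_fraction: float = 0.10
    species_offspring_cap: float = 0.10
    fitness_stop: float = 0.05
    p_mutation: float = 1.0
    selection_mode: str = "random"  # "random" | "tournament"
    speciation_enabled: bool = True
    seed: int = 0
    mutation: MutationConfig = field(default_factory=MutationConfig)
    crossover: CrossoverConfig = field(default_factory=CrossoverConfig)
    speciation: SpeciationState = field(default_factory=SpeciationState)
    objective: OscillatorTarget = field(default_factory=OscillatorTarget)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("elite_fraction", "cull_fraction", "species_offspring_cap", "p_mutation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.selection_mode not in ("random", "tournament"):
            raise ValueError("selection_mode must be 'random' or 'tournament'")
        if self.crossover.p_crossover + self.p_mutation < 1.0:
            raise ValueError(
                "p_crossover + p_mutation must be >= 1 so every non-elite "
                "offspring is crossed over, mutated, or both"
            )

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionConfig":
        d = dict(d)
        nested = {
            "mutation": MutationConfig,
            "crossover": CrossoverConfig,
            "speciation": SpeciationState,
            "objective": OscillatorTarget,
        }
        for key, typ in nested.items():
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "EvolutionConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    species_count: int
    population_size: int
    unique_fraction: float
    best_copies_fraction: float
    delta_t: float


@dataclass
class EvolutionResult:
    population: list[ReactionNetwork]
    species_bests: list[ReactionNetwork]
    records: list[GenerationRecord]
    config: EvolutionConfig
    stopped_early: bool


# ---------------------------------------------------------------------------
# Reproduction primitives
# ---------------------------------------------------------------------------


def allocate_offspring(
    groups: list[SpeciesGroup], population_size: int, cap: float = 0.10
) -> dict[int, int]:
    """Fitness-proportionate offspring quotas, capped per species.

    quota_s = round(fitness_s / Σ fitness * population_size), then clipped
    at floor(cap * population_size). Capped surplus is *not* redistributed.
    When every species scores zero, quotas are uniform.
    """
    total = sum(g.fitness for g in groups)
    cap_n = math.floor(cap * population_size)
    quotas: dict[int, int] = {}
    for g in groups:
        if total > 0:
            q = math.floor(g.fitness / total * population_size + 0.5)
        else:
            q = math.floor(population_size / len(groups) + 0.5)
        quotas[g.id] = min(q, cap_n)
    return quotas


def _sorted_members(group: SpeciesGroup) -> list[ReactionNetwork]:
    return sorted(
        group.members,
        key=lambda m: (-(m.fitness or 0.0), m.uid if m.uid is not None else 0),
    )


def select_elites(group: SpeciesGroup, quota: int, elite_fraction: float = 0.10) -> list[ReactionNetwork]:
    """Unmodified copies of the group's top members.

    Groups of more than 10 members pass on ceil(elite_fraction * size)
    elites; smaller groups pass on just their single best. Never more than
    the group's offspring quota. Fitness ties break toward lower uid.
    """
    if quota <= 0 or not group.members:
        return []
    ranked = _sorted_members(group)
    n = len(ranked)
    n_elite = 1 if n <= 10 else math.ceil(elite_fraction * n)
    return [m.copy() for m in ranked[: min(n_elite, quota)]]


def cull(group: SpeciesGroup, cull_fraction: float = 0.10) -> list[ReactionNetwork]:
    """Parent pool after removing the bottom floor(cull_fraction * size)."""
    ranked = _sorted_members(group)
    n_cut = math.floor(cull_fraction * len(ranked))
    return ranked[: len(ranked) - n_cut] if n_cut else ranked


def tournament_select(pool: list[ReactionNetwork], rng: np.random.Generator) -> ReactionNetwork:
    """The fitter of two uniform draws with replacement."""
    if not pool:
        raise ValueError("empty selection pool")
    a = pool[rng.integers(len(pool))]
    b = pool[rng.integers(len(pool))]
    return a if (a.fitness or 0.0) >= (b.fitness or 0.0) else b


def _select(pool, mode: str, rng) -> ReactionNetwork:
    if mode == "tournament":
        return tournament_select(pool, rng)
    return pool[rng.integers(len(pool))]


def _ordered_parents(a, b, rng):
    fa, fb = a.fitness or 0.0, b.fitness or 0.0
    if fa > fb:
        return a, b
    if fb > fa:
        return b, a
    return (a, b) if rng.random() < 0.5 else (b, a)


def next_generation(
    groups: list[SpeciesGroup],
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    quotas: dict[int, int] | None = None,
    evaluate=None,
) -> list[ReactionNetwork]:
    """Produce the next population from speciated, evaluated groups.

    Per species: elites are copied unmodified; the remaining quota is
    filled by drawing p ~ U(0,1) — p < p_crossover mates two parents from
    the culled survivor pool (elites included), and p >= 1 - p_mutation
    mutates the (crossed or selected) offspring. With the config constraint
    p_crossover + p_mutation >= 1, every non-elite offspring is changed.

    A species whose quota is exactly 1 instead gives its best network one
    trial mutation, kept only if it improves fitness (requires
    ``evaluate``; without it the unmodified best is copied).
    """
    if quotas is None:
        # the per-species cap exists to stop one species taking over; with a
        # single global group (speciation off) it must not bind
        cap = cfg.species_offspring_cap if cfg.speciation_enabled else 1.0
        quotas = allocate_offspring(groups, cfg.population_size, cap)
    offspring: list[ReactionNetwork] = []
    p_c = cfg.crossover.p_crossover
    for g in sorted(groups, key=lambda g: g.id):
        quota = quotas.get(g.id, 0)
        if quota <= 0:
            continue
        if quota == 1:
            best = g.best()
            child = genetic_ops.mutate(best, cfg.mutation, rng)
            if evaluate is not None:
                child.fitness = evaluate(child)
                keep = child.fitness > (best.fitness or 0.0)
            else:
                keep = False
            offspring.append(child if keep else best.copy())
            continue
        elites = select_elites(g, quota, cfg.elite_fraction)
        offspring.extend(elites)
        pool = cull(g, cfg.cull_fraction)
        if not pool:
            pool = [g.best()]
        for _ in range(quota - len(elites)):
            p = rng.random()
            crossed = p < p_c
            if crossed:
                a = _select(pool, cfg.selection_mode, rng)
                b = _select(pool, cfg.selection_mode, rng)
                if cfg.crossover.lenient_enabled and genetic_ops.fitness_within_window(
                    a.fitness or 0.0, b.fitness or 0.0, cfg.crossover.lenient_fitness_window
                ):
                    child = genetic_ops.crossover_lenient(a, b, cfg.crossover, rng)
                else:
                    fit, less = _ordered_parents(a, b, rng)
                    child = genetic_ops.crossover(fit, less, cfg.crossover, rng)
            else:
                child = _select(pool, cfg.selection_mode, rng).copy()
            if p >= 1.0 - cfg.p_mutation:
                child = genetic_ops.mutate(child, cfg.mutation, rng)
            elif not crossed:
                # unreachable under the validated constraint, but never let
                # an unmodified non-elite slip through
                child = genetic_ops.mutate(child, cfg.mutation, rng)
            child.fitness = None
            offspring.append(child)
    return offspring


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------


def _make_evaluator(cfg: EvolutionConfig, target: TimeSeriesTarget | None):
    if target is not None:
        return lambda net: timeseries_fitness(net, target)
    return lambda net: oscillator_fitness(net, cfg.objective)


def evolve(
    cfg: EvolutionConfig,
    target: TimeSeriesTarget | None = None,
    out_dir=None,
) -> EvolutionResult:
    """Run one evolution trial.

    Evolves toward the config's oscillator objective, or toward matching
    ``target`` when a time series is supplied. Stops at ``max_generations``
    or as soon as the best fitness reaches ``fitness_stop``. With
    ``out_dir`` set, writes one Antimony file per species best (with its
    fitness), the fully resolved settings JSON, and the per-generation
    record table.
    """
    rng = np.random.default_rng(cfg.seed)
    evaluate = _make_evaluator(cfg, target)
    uid_counter = 0

    population: list[ReactionNetwork] = []
    for _ in range(cfg.population_size):
        net = random_network(
            rng,
            n_species=cfg.n_species,
            n_reactions=cfg.n_reactions,
            type_probs=cfg.mutation.reaction_type_probs,
            rate_range=cfg.mutation.rate_range,
            init_conc_range=cfg.init_conc_range,
        )
        net.uid = uid_counter
        uid_counter += 1
        population.append(net)

    state = cfg.speciation
    groups: list[SpeciesGroup] = []
    records: list[GenerationRecord] = []
    stopped_early = False

    for generation in range(cfg.max_generations):
        for net in population:
            if net.fitness is None:
                net.fitness = evaluate(net)
            if net.uid is None:
                net.uid = uid_counter
                uid_counter += 1

        # unsimulable models score 0.0 and are removed from the population
        # outright (they would otherwise clog the parent pools)
        alive = [n for n in population if n.fitness > 0.0]
        if alive:
            population = alive

        if cfg.speciation_enabled:
            groups = assign_species(population, groups, state, rng)
            state = adapt_threshold(state, len(groups))
        else:
            rep = groups[0].representative if groups else population[0]
            groups = [SpeciesGroup(id=0, representative=rep, members=list(population))]

        best_fit = max((n.fitness or 0.0) for n in population)
        uniq, best_copies = diversity_metrics(population)
        records.append(
            GenerationRecord(
                generation=generation,
                best_fitness=best_fit,
                species_count=len(groups),
                population_size=len(population),
                unique_fraction=uniq,
                best_copies_fraction=best_copies,
                delta_t=state.delta_t,
            )
        )
        if best_fit >= cfg.fitness_stop:
            stopped_early = True
            break
        if generation == cfg.max_generations - 1:
            break

        # carry representatives forward: best member of each live group
        for g in groups:
            g.representative = g.best()
        population = next_generation(groups, cfg, rng, evaluate=evaluate)
        if not population:  # every species capped/zeroed out; reseed from bests
            population = [g.best().copy() for g in groups]
        for net in population:
            if net.uid is None:
                net.uid = uid_counter
                uid_counter += 1

    species_bests = [g.best() for g in sorted(groups, key=lambda g: g.id)]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_json(out / "settings.json")
        for g in sorted(groups, key=lambda g: g.id):
            text = write_antimony(g.best(), fitness_comment=True)
            (out / f"species_{g.id}_best.ant").write_text(text)
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out / "generations.csv", index=False
        )

    return EvolutionResult(
        population=population,
        species_bests=species_bests,
        records=records,
        config=cfg,
        stopped_early=stopped_early,
    )
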