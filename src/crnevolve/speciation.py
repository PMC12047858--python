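"""Speciation: grouping networks by topological similarity.

The compatibility distance between two networks is δ = M/N, where N is the
active-reaction count of the larger network and M the number of its active
reactions absent from the smaller one. Networks whose distance to a species
representative falls below an adaptive threshold δ_t join that species;
otherwise a new species is founded. δ_t is nudged by a fixed step ε each
generation to steer the species count toward a target (10 by default).
The distance is genotypic (all reaction records count, as for NEAT's
disabled genes); the diversity metrics are phenotypic (active reactions
only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import ReactionNetwork

__all__ = [
    "SpeciationState",
    "SpeciesGroup",
    "distance",
    "assign_species",
    "adapt_threshold",
    "diversity_metrics",
]


@dataclass(frozen=True)
class SpeciationState:
    """Adaptive-threshold controller state."""

    delta_t: float = 0.3
    epsilon: float = 0.05
    target_species: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_t <= 1.0:
            raise ValueError("delta_t must be in [0,1]")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.target_species < 1:
            raise ValueError("target_species must be >= 1")


@dataclass
class SpeciesGroup:
    """A species: its members this generation and a representative.

    The representative is the best member of the previous generation (the
    founder, for a species created this generation); new networks are
    compared against it. The group's fitness is its best member's fitness.
    """

    id: int
    representative: ReactionNetwork
    members: list[ReactionNetwork] = field(default_factory=list)
    offspring_quota: int = 0

    @property
    def fitness(self) -> float:
        return max((m.fitness or 0.0) for m in self.members) if self.members else 0.0

    def best(self) -> ReactionNetwork:
        """Fittest member; ties broken by lower uid for determinism."""
        return min(
            self.members,
            key=lambda m: (-(m.fitness or 0.0), m.uid if m.uid is not None else 0),
        )


def distance(net_a: ReactionNetwork, net_b: ReactionNetwork) -> float:
    """Compatibility distance δ = M/N over *recorded* reaction keys.

    Every reaction record counts, active or not — deactivated reactions are
    heritable genes and two lineages that share history are compatible, the
    same convention NEAT uses for disabled connection genes. (Active-only
    distance collapses for small evolved networks: with one or two active
    reactions δ can only take the values 0 and 1, and the adaptive
    threshold loses control of the species count.) Rate constants are
    ignored. Symmetric, bounded in [0,1], zero iff the recorded key sets
    are equal. A network with no recorded reactions is at distance 1 from
    any non-empty network (and 0 from another empty one).
    """
    a = frozenset(r.key for r in net_a.reactions)
    b = frozenset(r.key for r in net_b.reactions)
    if len(a) < len(b):
        a, b = b, a
    if not a:
        return 0.0
    if not b:
        return 1.0
    return len(a - b) / len(a)


def assign_species(
    population: list[ReactionNetwork],
    previous_groups: list[SpeciesGroup],
    state: SpeciationState,
    rng: np.random.Generator | None = None,
) -> list[SpeciesGroup]:
    """Sort a population into species against last generation's groups.

    Each network is compared to representatives in ascending group-id
    order; the first with δ < δ_t claims it. Failing all, a new species is
    founded with the network as representative — and is immediately
    available to later networks of the same generation. Groups that end up
    empty are dropped.
    """
    groups = [
        SpeciesGroup(id=g.id, representative=g.representative)
        for g in sorted(previous_groups, key=lambda g: g.id)
    ]
    next_id = max((g.id for g in groups), default=-1) + 1
    for net in population:
        for g in groups:
            if distance(net, g.representative) < state.delta_t:
                g.members.append(net)
                net.species_group = g.id
                break
        else:
            g = SpeciesGroup(id=next_id, representative=net, members=[net])
            net.species_group = g.id
            groups.append(g)
            next_id += 1
    return [g for g in groups if g.members]


def adapt_threshold(state: SpeciationState, current_species_count: int) -> SpeciationState:
    """Step δ_t toward the target species count, clamped to [0,1].

    More species than the target → raise δ_t (coarser grouping); fewer →
    lower it; exactly on target → unchanged.
    """
    if current_species_count < 1:
        raise ValueError("current_species_count must be >= 1")
    if current_species_count > state.target_species:
        d = state.delta_t + state.epsilon
    elif current_species_count < state.target_species:
        d = state.delta_t - state.epsilon
    else:
        d = state.delta_t
    return replace(state, delta_t=float(np.clip(d, 0.0, 1.0)))


def diversity_metrics(population: list[ReactionNetwork]) -> tuple[float, float]:
    """(unique_fraction, best_copies_fraction) of a population.

    A network is unique if its active key set differs from every other
    member's. best_copies_fraction counts members whose active key set
    equals the fittest network's (ties on fitness broken by lower uid).
    """
    if not population:
        raise ValueError("population must be non-empty")
    keysets = [net.active_keys() for net in population]
    counts: dict[frozenset, int] = {}
    for ks in keysets:
        counts[ks] = counts.get(ks, 0) + 1
    unique = sum(1 for ks in keysets if counts[ks] == 1)
    best = min(
        range(len(population)),
        key=lambda i: (
            -(population[i].fitness or 0.0),
            population[i].uid if population[i].uid is not None else 0,
        ),
    )
    best_copies = counts[keysets[best]]
    n = len(population)
    return unique / n, best_copies / n
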