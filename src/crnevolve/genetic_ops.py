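"""Mutation and crossover operators.

Mutation comes in two flavours: rate-constant perturbation (multiplicative
±20% by default, occasionally a full redraw) and topology change (add a
random reaction or switch an existing one off, 50/50). Deleted reactions
stay in the genome as inactive records and can reactivate during crossover.

Crossover follows the NEAT convention adapted to reaction networks: the
offspring inherits the fitter parent's topology; reactions shared by both
parents take their rate constant from a randomly chosen parent. A second,
*lenient* variant for parents of near-equal fitness inherits unshared
reactions with probability 0.5 instead of strictly following the fitter
parent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import (
    DEFAULT_RATE_RANGE,
    DEFAULT_TYPE_PROBS,
    Reaction,
    ReactionNetwork,
    random_reaction,
    reaction_key,
)

__all__ = [
    "MutationConfig",
    "CrossoverConfig",
    "mutate_rate_constant",
    "mutate_reaction",
    "mutate",
    "crossover",
    "crossover_lenient",
]


@dataclass(frozen=True)
class MutationConfig:
    p_rate_mutation: float = 0.6
    p_reaction_mutation: float = 0.4
    percent_range: float = 0.20        # symmetric: k -> k*(1 ± u), u <= this
    redraw_probability: float = 0.1    # chance of a full redraw instead
    redraw_range: tuple[float, float] = DEFAULT_RATE_RANGE
    reaction_type_probs: tuple[float, float, float, float] = DEFAULT_TYPE_PROBS
    rate_range: tuple[float, float] = DEFAULT_RATE_RANGE

    def __post_init__(self) -> None:
        for name in ("p_rate_mutation", "p_reaction_mutation", "redraw_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not self.percent_range > 0:
            raise ValueError("percent_range must be positive")
        lo, hi = self.redraw_range
        if not 0 <= lo < hi:
            raise ValueError("redraw_range must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class CrossoverConfig:
    p_crossover: float = 0.0
    reactivation_probability: float = 0.25
    lenient_enabled: bool = False
    lenient_fitness_window: float = 0.05
    lenient_inherit_probability: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "p_crossover",
            "reactivation_probability",
            "lenient_fitness_window",
            "lenient_inherit_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


def mutate_rate_constant(
    r: Reaction, cfg: MutationConfig, rng: np.random.Generator
) -> Reaction:
    """Perturb one rate constant.

    With probability 1 - redraw_probability the constant is scaled by a
    uniform factor in [1 - percent_range, 1 + percent_range]; otherwise it
    is redrawn uniformly from redraw_range. The result can never go
    negative (the multiplicative path keeps the sign, and a zero constant
    is a fixed point of it).
    """
    if rng.random() < cfg.redraw_probability:
        k = float(rng.uniform(*cfg.redraw_range))
    else:
        k = r.rate_constant * (1.0 + float(rng.uniform(-cfg.percent_range, cfg.percent_range)))
    return replace(r, rate_constant=max(k, 0.0))


def mutate_reaction(
    net: ReactionNetwork, cfg: MutationConfig, rng: np.random.Generator
) -> ReactionNetwork:
    """Topology mutation: add a random reaction or deactivate one, 50/50.

    Additions merge into an existing duplicate key by summing rate
    constants. Deletion only switches the reaction off — the record stays.
    A network with no active reaction falls back to addition, so mutation
    always leaves a live dynamical system.
    """
    out = net.copy()
    active_idx = [i for i, r in enumerate(out.reactions) if r.active]
    delete = rng.random() < 0.5 and active_idx
    if delete:
        i = active_idx[rng.integers(len(active_idx))]
        out.reactions[i] = replace(out.reactions[i], active=False)
    else:
        out.add_reaction(
            random_reaction(out.species, rng, cfg.reaction_type_probs, cfg.rate_range)
        )
    return out


def mutate(
    net: ReactionNetwork,
    cfg: MutationConfig,
    rng: np.random.Generator,
    ensure_change: bool = True,
) -> ReactionNetwork:
    """Apply rate and/or topology mutation, each with its own probability.

    The rate path perturbs one uniformly chosen active reaction. With
    ``ensure_change`` the draw repeats until at least one mutation fires,
    so a caller that asked for a mutated offspring always gets one.
    """
    out = net.copy()
    while True:
        applied = False
        if rng.random() < cfg.p_rate_mutation:
            active_idx = [i for i, r in enumerate(out.reactions) if r.active]
            if active_idx:
                i = active_idx[rng.integers(len(active_idx))]
                out.reactions[i] = mutate_rate_constant(out.reactions[i], cfg, rng)
                applied = True
        if rng.random() < cfg.p_reaction_mutation:
            out = mutate_reaction(out, cfg, rng)
            applied = True
        if applied or not ensure_change:
            break
        if cfg.p_rate_mutation == 0.0 and cfg.p_reaction_mutation == 0.0:
            break  # nothing can ever fire; give up rather than loop
    out.fitness = None
    out.uid = None
    return out


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------


def _maybe_reactivate(r: Reaction, cfg: CrossoverConfig, rng: np.random.Generator) -> Reaction:
    if not r.active and rng.random() < cfg.reactivation_probability:
        return replace(r, active=True)
    return r


def crossover(
    fit_parent: ReactionNetwork,
    less_fit_parent: ReactionNetwork,
    cfg: CrossoverConfig,
    rng: np.random.Generator,
) -> ReactionNetwork:
    """NEAT-style crossover: the fitter parent's structure is preserved.

    Every reaction of the fitter parent is passed down; for keys present in
    both parents the rate constant comes from a uniformly chosen parent.
    Reactions private to the less fit parent are dropped. Inherited
    inactive reactions reactivate with ``reactivation_probability``.
    Initial concentrations come from the fitter parent. Callers must order
    the parents (ties broken randomly upstream).
    """
    if len(fit_parent.species) != len(less_fit_parent.species):
        raise ValueError("parents must have the same species count")
    child = ReactionNetwork(
        species=fit_parent.species,
        initial_concentrations=fit_parent.initial_concentrations,
    )
    other = {reaction_key(r): r for r in less_fit_parent.reactions}
    for r in fit_parent.reactions:
        key = reaction_key(r)
        if key in other and rng.random() < 0.5:
            r = replace(r, rate_constant=other[key].rate_constant)
        child.reactions.append(_maybe_reactivate(r, cfg, rng))
    return child


def crossover_lenient(
    parent_a: ReactionNetwork,
    parent_b: ReactionNetwork,
    cfg: CrossoverConfig,
    rng: np.random.Generator,
) -> ReactionNetwork:
    """Crossover for parents of near-equal fitness.

    Shared keys are always inherited (rate constant from a random parent);
    keys private to either parent are inherited with
    ``lenient_inherit_probability``. The caller is responsible for checking
    the fitness window (see :func:`fitness_within_window`).
    """
    if len(parent_a.species) != len(parent_b.species):
        raise ValueError("parents must have the same species count")
    child = ReactionNetwork(
        species=parent_a.species,
        initial_concentrations=parent_a.initial_concentrations,
    )
    b_map = {reaction_key(r): r for r in parent_b.reactions}
    a_keys = {reaction_key(r) for r in parent_a.reactions}
    for r in parent_a.reactions:
        key = reaction_key(r)
        if key in b_map:
            if rng.random() < 0.5:
                r = replace(r, rate_constant=b_map[key].rate_constant)
            child.reactions.append(_maybe_reactivate(r, cfg, rng))
        elif rng.random() < cfg.lenient_inherit_probability:
            child.reactions.append(_maybe_reactivate(r, cfg, rng))
    for key, r in b_map.items():
        if key not in a_keys and rng.random() < cfg.lenient_inherit_probability:
            child.reactions.append(_maybe_reactivate(r, cfg, rng))
    return child


def fitness_within_window(a: float, b: float, window: float) -> bool:
    """True when two fitness scores are within ``window`` of each other,
    relative to the larger score."""
    hi = max(a, b)
    if hi <= 0.0:
        return True
    return abs(a - b) <= window * hi
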