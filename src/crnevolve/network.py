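"""Core data structures for mass-action reaction networks.

A network is a fixed set of chemical species plus a variable-length list of
mass-action reactions. Each reaction has one or two reactants, one or two
products, a non-negative rate constant and an *active* flag. Inactive
reactions contribute nothing to the dynamics but are kept as heritable
history (NEAT-style gene disabling) and may later be reactivated.

Reaction identity ("key") depends only on the reactant and product multisets;
rate constants and activity are deliberately excluded, so that structural
comparisons between networks are purely topological.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "reaction_key",
    "random_reaction",
    "random_network",
    "write_antimony",
    "parse_antimony",
    "AntimonyParseError",
]

#: Sampling weights for the four mass-action shapes
#: (uni-uni, uni-bi, bi-uni, bi-bi).
DEFAULT_TYPE_PROBS = (0.1, 0.4, 0.4, 0.1)

#: Default range rate constants are drawn from.
DEFAULT_RATE_RANGE = (0.1, 50.0)

#: Default range for random initial concentrations.
DEFAULT_INIT_CONC_RANGE = (0.0, 10.0)

_REACTION_SHAPES = ((1, 1), (1, 2), (2, 1), (2, 2))


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactants`` and ``products`` each hold one or two species names;
    repeats encode stoichiometry (``("S0", "S0") -> ("S1",)`` is 2 S0 -> S1).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    active: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError(f"reaction needs 1-2 reactants, got {self.reactants!r}")
        if not 1 <= len(self.products) <= 2:
            raise ValueError(f"reaction needs 1-2 products, got {self.products!r}")
        if not self.rate_constant >= 0:
            raise ValueError(f"rate constant must be >= 0, got {self.rate_constant!r}")
        object.__setattr__(
            self, "_key", (tuple(sorted(self.reactants)), tuple(sorted(self.products)))
        )

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return self._key


def reaction_key(r: Reaction) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Canonical identity of a reaction.

    Two reactions are identical iff their reactant multisets and product
    multisets match; order within each side, the rate constant and the
    active flag are ignored.
    """
    return r._key


@dataclass
class ReactionNetwork:
    """A mass-action network: fixed species, variable reaction list.

    Invariants maintained by :meth:`add_reaction`:

    * no two stored reactions share a key (duplicates merge by summing
      rate constants);
    * all reactant/product names are members of ``species``.

    ``fitness`` is ``None`` until evaluated. ``uid`` and ``species_group``
    are bookkeeping for the evolutionary loop.
    """

    species: tuple[str, ...]
    initial_concentrations: tuple[float, ...]
    reactions: list[Reaction] = field(default_factory=list)
    fitness: float | None = None
    uid: int | None = None
    species_group: int | None = None

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.initial_concentrations = tuple(float(c) for c in self.initial_concentrations)
        if len(self.initial_concentrations) != len(self.species):
            raise ValueError("one initial concentration per species required")
        if any(c < 0 for c in self.initial_concentrations):
            raise ValueError("initial concentrations must be non-negative")
        staged, self.reactions = list(self.reactions), []
        for r in staged:
            self.add_reaction(r)

    # -- structural queries -------------------------------------------------

    def active_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.active]

    def active_keys(self) -> frozenset:
        return frozenset(reaction_key(r) for r in self.reactions if r.active)

    def find(self, key) -> int | None:
        """Index of the stored reaction with this key, or None."""
        for i, r in enumerate(self.reactions):
            if reaction_key(r) == key:
                return i
        return None

    # -- mutation helpers ---------------------------------------------------

    def add_reaction(self, r: Reaction) -> None:
        """Insert a reaction, merging duplicates by key.

        If a reaction with the same key already exists its rate constant is
        incremented by ``r.rate_constant``; a merge into an inactive
        duplicate also reactivates it.
        """
        unknown = (set(r.reactants) | set(r.products)) - set(self.species)
        if unknown:
            raise ValueError(f"reaction uses unknown species {sorted(unknown)}")
        i = self.find(reaction_key(r))
        if i is None:
            self.reactions.append(r)
        else:
            old = self.reactions[i]
            self.reactions[i] = replace(
                old, rate_constant=old.rate_constant + r.rate_constant, active=True
            )

    def copy(self) -> "ReactionNetwork":
        """Deep-enough copy (Reaction is frozen, so the list copy suffices)."""
        return ReactionNetwork(
            species=self.species,
            initial_concentrations=self.initial_concentrations,
            reactions=list(self.reactions),
            fitness=self.fitness,
            uid=self.uid,
            species_group=self.species_group,
        )


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------


def random_reaction(
    species_list,
    rng: np.random.Generator,
    type_probs=DEFAULT_TYPE_PROBS,
    rate_range=DEFAULT_RATE_RANGE,
) -> Reaction:
    """Draw a random reaction.

    The shape (uni-uni / uni-bi / bi-uni / bi-bi) is drawn from
    ``type_probs``; every reactant and product slot is then filled uniformly
    *with replacement* from ``species_list`` (so A+A -> B and A -> A+B are
    possible), and the rate constant uniformly from ``rate_range``.
    """
    species_list = list(species_list)
    if not species_list:
        raise ValueError("species_list must be non-empty")
    probs = np.asarray(type_probs, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("type_probs must be 4 probabilities summing to 1")
    lo, hi = rate_range
    if not 0 <= lo < hi:
        raise ValueError("rate_range must satisfy 0 <= lo < hi")
    n_react, n_prod = _REACTION_SHAPES[rng.choice(4, p=probs)]
    reactants = tuple(species_list[i] for i in rng.integers(len(species_list), size=n_react))
    products = tuple(species_list[i] for i in rng.integers(len(species_list), size=n_prod))
    return Reaction(reactants, products, float(rng.uniform(lo, hi)), active=True)


def random_network(
    rng: np.random.Generator,
    n_species: int = 3,
    n_reactions: int = 5,
    type_probs=DEFAULT_TYPE_PROBS,
    rate_range=DEFAULT_RATE_RANGE,
    init_conc_range=DEFAULT_INIT_CONC_RANGE,
) -> ReactionNetwork:
    """Generate a random network with ``n_species`` species S0..S{n-1}.

    ``n_reactions`` draws are made; the stored count can be lower because
    duplicate keys merge. Initial concentrations are uniform in
    ``init_conc_range``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_reactions < 1:
        raise ValueError("need at least 1 reaction")
    species = tuple(f"S{i}" for i in range(n_species))
    concs = tuple(float(c) for c in rng.uniform(*init_conc_range, size=n_species))
    net = ReactionNetwork(species=species, initial_concentrations=concs)
    for _ in range(n_reactions):
        net.add_reaction(random_reaction(species, rng, type_probs, rate_range))
    return net


# ---------------------------------------------------------------------------
# Antimony-dialect I/O
# ---------------------------------------------------------------------------


class AntimonyParseError(ValueError):
    """Raised for text not in the subset dialect emitted by write_antimony."""


def write_antimony(net: ReactionNetwork, fitness_comment: bool = False) -> str:
    """Serialise the *active* part of a network as Antimony text.

    One line per active reaction (``J0: A + B -> C; k0*A*B;``), followed by
    ``kN = value`` rate assignments and per-species initial concentrations.
    Numbers are written at full repr precision so files round-trip exactly.
    """
    lines = []
    active = net.active_reactions()
    for i, r in enumerate(active):
        lhs = " + ".join(r.reactants)
        rhs = " + ".join(r.products)
        rate = "*".join([f"k{i}", *r.reactants])
        lines.append(f"J{i}: {lhs} -> {rhs}; {rate};")
    if active:
        lines.append("")
    for i, r in enumerate(active):
        lines.append(f"k{i} = {r.rate_constant!r}")
    if active:
        lines.append("")
    for name, conc in zip(net.species, net.initial_concentrations):
        lines.append(f"{name} = {conc!r}")
    if fitness_comment and net.fitness is not None:
        lines.append(f"# fitness: {net.fitness!r}")
    return "\n".join(lines) + "\n"


_REACTION_RE = re.compile(
    r"^J\d+:\s*(?P<lhs>[^;>]+?)\s*->\s*(?P<rhs>[^;]+?)\s*;\s*(?P<rate>[^;]+?)\s*;$"
)
_ASSIGN_RE = re.compile(r"^(?P<name>[A-Za-z_]\w*)\s*=\s*(?P<value>\S+)$")


def parse_antimony(text: str) -> ReactionNetwork:
    """Parse the dialect produced by :func:`write_antimony`.

    Returns a network whose active part serialises back to an equivalent
    document. A trailing ``# fitness:`` comment, if present, populates
    ``fitness``.
    """
    reactions: list[tuple[tuple[str, ...], tuple[str, ...], str]] = []
    assignments: dict[str, float] = {}
    order: list[str] = []
    fitness = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"^#\s*fitness:\s*(\S+)$", line)
            if m:
                fitness = float(m.group(1))
            continue
        m = _REACTION_RE.match(line)
        if m:
            lhs = tuple(s.strip() for s in m.group("lhs").split("+"))
            rhs = tuple(s.strip() for s in m.group("rhs").split("+"))
            rate_name = m.group("rate").split("*")[0].strip()
            if not all(lhs) or not all(rhs):
                raise AntimonyParseError(f"line {lineno}: malformed species list: {raw!r}")
            reactions.append((lhs, rhs, rate_name))
            continue
        m = _ASSIGN_RE.match(line)
        if m:
            name = m.group("name")
            try:
                value = float(m.group("value"))
            except ValueError as exc:
                raise AntimonyParseError(f"line {lineno}: bad number in {raw!r}") from exc
            assignments[name] = value
            if name not in order:
                order.append(name)
            continue
        raise AntimonyParseError(f"line {lineno}: unrecognised line {raw!r}")

    rate_names = {rn for _, _, rn in reactions}
    species = [n for n in order if n not in rate_names]
    mentioned = {s for lhs, rhs, _ in reactions for s in (*lhs, *rhs)}
    missing = mentioned - set(species)
    if missing:
        raise AntimonyParseError(f"species {sorted(missing)} lack initial concentrations")
    if not species:
        raise AntimonyParseError("no species assignments found")
    net = ReactionNetwork(
        species=tuple(species),
        initial_concentrations=tuple(assignments[s] for s in species),
        fitness=fitness,
    )
    for lhs, rhs, rate_name in reactions:
        if rate_name not in assignments:
            raise AntimonyParseError(f"rate constant {rate_name!r} is never assigned")
        net.add_reaction(Reaction(lhs, rhs, assignments[rate_name], active=True))
    return net
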