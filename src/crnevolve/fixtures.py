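"""Programmatic test inputs with machine-checkable expected properties.

These are first-class generators, not canned data: the Lotka-Volterra
predator-prey system expressed in the 1-2 reactant/product encoding, a
rejection-sampled ground-truth network with its time series (for the
fitting mode), and adversarial networks exercising the failure paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitness import TimeSeriesTarget
from .network import Reaction, ReactionNetwork, random_network
from .simulation import simulate

__all__ = ["Fixture", "lotka_volterra", "ground_truth_fixture", "adversarial_cases"]


@dataclass
class Fixture:
    name: str
    network: ReactionNetwork
    expected: dict = field(default_factory=dict)


def lotka_volterra(k1: float = 1.0, k2: float = 1.0, k3: float = 1.0) -> Fixture:
    """Predator-prey dynamics in mass-action form.

    S0 (prey) grows autocatalytically (S0 -> 2 S0, k1), predation converts
    prey to predator (S0 + S1 -> 2 S1, k2), and predators are removed into
    the inert sink S2 (S1 -> S2, k3). The prey/predator subsystem has the
    classic interior fixed point (k3/k2, k1/k2) with purely imaginary
    eigenvalues ±i·sqrt(k1*k3) — a neutrally stable center.
    """
    if min(k1, k2, k3) <= 0:
        raise ValueError("all rate constants must be positive")
    x_star, y_star = k3 / k2, k1 / k2
    net = ReactionNetwork(
        species=("S0", "S1", "S2"),
        # start off the fixed point so trajectories visibly cycle
        initial_concentrations=(1.2 * x_star, 0.8 * y_star, 1.0),
        reactions=[
            Reaction(("S0",), ("S0", "S0"), k1),
            Reaction(("S0", "S1"), ("S1", "S1"), k2),
            Reaction(("S1",), ("S2",), k3),
        ],
    )
    return Fixture(
        name="lotka_volterra",
        network=net,
        expected={
            "fixed_point": (x_star, y_star),
            "eigen_imag": math.sqrt(k1 * k3),
            "sink_species": "S2",
        },
    )


def ground_truth_fixture(
    seed: int = 0,
    t_end: float = 10.0,
    n_points: int = 51,
) -> tuple[Fixture, TimeSeriesTarget]:
    """A random 3-species, 5-reaction network with non-degenerate dynamics,
    plus its own sampled time series — the input for the fitting mode.

    Rejection-sampled until the simulation succeeds and at least one
    species actually moves (range > 0.1 over the window).
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_points)
    for _ in range(1000):
        net = random_network(rng, n_species=3, n_reactions=5)
        traj = simulate(net, t_end=t_end, t_eval=times)
        if not traj.success:
            continue
        span = traj.concentrations.max(axis=0) - traj.concentrations.min(axis=0)
        if span.max() > 0.1:
            target = TimeSeriesTarget(
                times=tuple(times), observed=tuple(map(tuple, traj.concentrations))
            )
            return Fixture(name=f"ground_truth_seed{seed}", network=net), target
    raise RuntimeError("could not sample a non-degenerate ground-truth network")


def adversarial_cases() -> list[Fixture]:
    """Networks exercising failure and edge paths."""
    # exponential autocatalysis S0 -> 2 S0: x(t) = x0*exp(k*t) overruns the
    # blow-up limit well inside the fitness window
    blowup = ReactionNetwork(
        species=("S0", "S1"),
        initial_concentrations=(5.0, 0.0),
        reactions=[Reaction(("S0",), ("S0", "S0"), 10.0)],
    )
    empty = ReactionNetwork(
        species=("S0", "S1", "S2"),
        initial_concentrations=(1.0, 1.0, 1.0),
        reactions=[],
    )
    dup = ReactionNetwork(
        species=("S0", "S1"),
        initial_concentrations=(1.0, 0.0),
        reactions=[Reaction(("S0",), ("S1",), 3.0)],
    )
    return [
        Fixture("finite_time_blowup", blowup, {"simulate_success": False, "fitness": 0.0}),
        Fixture("zero_active_reactions", empty, {"distance_vs_nonempty": 1.0}),
        Fixture(
            "duplicate_key_merge",
            dup,
            {"add": Reaction(("S0",), ("S1",), 2.0), "merged_rate": 5.0},
        ),
    ]
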