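"""Mass-action dynamics: ODE right-hand sides, integration, steady states.

Every active reaction contributes a rate ``v = k * prod(reactant
concentrations, with multiplicity)``; a duplicated reactant (A+A -> ...)
gives ``v = k*[A]^2`` and consumes A at ``2v``. The right-hand side, its
analytic Jacobian and the net stoichiometry matrix are assembled once per
network and reused across solver calls.

Failure semantics matter here: candidate networks produced by the
evolutionary search routinely blow up in finite time or defeat the
integrator. Those are *expected* outcomes, reported as ``success=False``
on the trajectory (and fitness 0 downstream), never as exceptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import ode, solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork

__all__ = [
    "Trajectory",
    "CompiledNetwork",
    "compile_network",
    "build_rhs",
    "simulate",
    "steady_state",
    "jacobian",
    "eigenvalues",
]

#: Concentration magnitude treated as a finite-time blow-up.
BLOWUP_LIMIT = 1e7

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9

#: Cap on internal integrator steps per solve; a breach counts as failure.
MAX_STEPS = 20_000


@dataclass
class Trajectory:
    times: np.ndarray
    concentrations: np.ndarray  # shape (len(times), n_species)
    success: bool

    def to_csv(self, path, species_names=None) -> None:
        """Write the trajectory as a delimited table (time, S0, S1, ...)."""
        import pandas as pd

        names = species_names or [f"S{i}" for i in range(self.concentrations.shape[1])]
        df = pd.DataFrame(self.concentrations, columns=list(names))
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


@dataclass
class CompiledNetwork:
    """Index-array form of a network's active reactions.

    ``r1``/``r2`` are reactant indices (``r2`` is -1 for uni-molecular
    rates), ``stoich`` is the (n_species, n_reactions) net stoichiometry
    matrix.
    """

    n_species: int
    k: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    stoich: np.ndarray

    def rates(self, x: np.ndarray) -> np.ndarray:
        v = self.k * x[self.r1]
        bi = self.r2 >= 0
        v[bi] *= x[self.r2[bi]]
        return v

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(np.asarray(x, dtype=float))

    def jac(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the mass-action right-hand side."""
        x = np.asarray(x, dtype=float)
        n_r = len(self.k)
        dv = np.zeros((n_r, self.n_species))
        for j in range(n_r):
            a, b = self.r1[j], self.r2[j]
            if b < 0:
                dv[j, a] += self.k[j]
            elif a == b:
                dv[j, a] += 2.0 * self.k[j] * x[a]
            else:
                dv[j, a] += self.k[j] * x[b]
                dv[j, b] += self.k[j] * x[a]
        return self.stoich @ dv

    def make_fast_rhs(self):
        """Plain-Python RHS closure for the integrator hot path.

        Equivalent to :meth:`rhs` (the tests assert this); list arithmetic
        beats numpy fancy indexing at the 2-10 reaction sizes evolved here.
        """
        n = self.n_species
        reacts = [
            (
                float(self.k[j]),
                int(self.r1[j]),
                int(self.r2[j]),
                [(i, float(self.stoich[i, j])) for i in range(n) if self.stoich[i, j]],
            )
            for j in range(len(self.k))
        ]

        def rhs(x):
            dx = [0.0] * n
            for k, a, b, eff in reacts:
                v = k * x[a]
                if b >= 0:
                    v *= x[b]
                for i, s in eff:
                    dx[i] += s * v
            return dx

        return rhs

    def sink_species(self) -> np.ndarray:
        """Boolean mask of species that influence nothing downstream.

        A species is an inert sink if it is not a reactant of any active
        reaction with a nonzero net effect: its concentration then appears
        in no rate law that changes any species, so the remaining system is
        self-contained and the sink merely accumulates (or sits still).
        Dynamically inert reactions (net stoichiometry zero, e.g. A -> A)
        are ignored.
        """
        mask = np.ones(self.n_species, dtype=bool)
        for j in range(len(self.k)):
            if not np.any(self.stoich[:, j]):
                continue
            mask[self.r1[j]] = False
            if self.r2[j] >= 0:
                mask[self.r2[j]] = False
        return mask


def compile_network(net: ReactionNetwork) -> CompiledNetwork:
    index = {s: i for i, s in enumerate(net.species)}
    active = net.active_reactions()
    n_r = len(active)
    k = np.empty(n_r)
    r1 = np.empty(n_r, dtype=np.intp)
    r2 = np.full(n_r, -1, dtype=np.intp)
    stoich = np.zeros((len(net.species), n_r))
    for j, r in enumerate(active):
        k[j] = r.rate_constant
        ridx = [index[s] for s in r.reactants]
        r1[j] = ridx[0]
        if len(ridx) == 2:
            r2[j] = ridx[1]
        for i in ridx:
            stoich[i, j] -= 1.0
        for s in r.products:
            stoich[index[s], j] += 1.0
    return CompiledNetwork(len(net.species), k, r1, r2, stoich)


def build_rhs(net: ReactionNetwork):
    """Return ``f(x) -> dx/dt`` for the network's active reactions."""
    return compile_network(net).rhs


def simulate(
    net: ReactionNetwork,
    t_end: float,
    n_points: int = 100,
    t_eval=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the network over [0, t_end] with a stiff-capable solver.

    Uses LSODA (automatic stiff/non-stiff switching) with the analytic
    Jacobian. Any dynamical failure — solver non-convergence, step-cap
    breach, NaN, or a concentration exceeding ``BLOWUP_LIMIT`` — yields
    ``success=False`` with whatever prefix of the trajectory was computed.
    Small negative round-off values are clamped to zero.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    compiled = compile_network(net)
    x0 = np.asarray(net.initial_concentrations, dtype=float)

    ts = [0.0]
    xs = [x0]
    ok = True
    fast_rhs = compiled.make_fast_rhs()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(all="ignore"):
            solver = ode(lambda t, x: fast_rhs(x), lambda t, x: compiled.jac(x))
            solver.set_integrator(
                "lsoda", rtol=rtol, atol=atol, nsteps=MAX_STEPS, with_jacobian=True
            )
            solver.set_initial_value(x0, 0.0)
            for t in t_eval:
                if t <= 0.0:
                    continue
                x = solver.integrate(t)
                if (
                    not solver.successful()
                    or not np.all(np.isfinite(x))
                    or np.max(np.abs(x)) > BLOWUP_LIMIT
                ):
                    ok = False
                    break
                ts.append(t)
                xs.append(np.array(x))
    conc = np.clip(np.vstack(xs), 0.0, None)
    times = np.array(ts)
    if t_eval[0] > 0.0:  # caller asked for a grid not anchored at 0
        times, conc = times[1:], conc[1:]
    return Trajectory(times=times, concentrations=conc, success=ok)


def jacobian(net: ReactionNetwork, x) -> np.ndarray:
    """Analytic Jacobian of the mass-action RHS at state ``x``."""
    return compile_network(net).jac(np.asarray(x, dtype=float))


def eigenvalues(matrix: np.ndarray) -> np.ndarray:
    return np.linalg.eigvals(np.asarray(matrix, dtype=float))


def steady_state(
    net: ReactionNetwork,
    guess=None,
    t_horizon: float = 50.0,
    tol: float = 1e-9,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> np.ndarray | None:
    """Locate a steady state: integrate long, then refine by root finding.

    The root condition is imposed on the *recurrent* subsystem only:
    species that never appear as reactants of a dynamically effective
    reaction (pure sinks) receive mass but influence nothing, so their
    derivatives are not required to vanish; they are reported at their
    trajectory endpoint value. Requires ``||rhs||_inf < tol`` on the
    recurrent species; returns ``None`` when no root converges after
    ``n_restarts`` perturbed retries.
    """
    compiled = compile_network(net)
    n = compiled.n_species
    sink = compiled.sink_species()
    dyn = ~sink

    if guess is not None:
        endpoint = np.asarray(guess, dtype=float)
    else:
        traj = simulate(net, t_end=t_horizon, n_points=20)
        endpoint = traj.concentrations[-1]
        if not traj.success and len(traj.times) < 2:
            return None

    if rng is None:
        rng = np.random.default_rng(0)

    def reduced_rhs(xd):
        x = endpoint.copy()
        x[dyn] = xd
        return compiled.rhs(x)[dyn]

    def reduced_jac(xd):
        x = endpoint.copy()
        x[dyn] = xd
        return compiled.jac(x)[np.ix_(dyn, dyn)]

    if not np.any(dyn):  # every species is a sink: nothing to solve
        x = endpoint.copy()
        return x

    start = endpoint[dyn]
    for attempt in range(n_restarts + 1):
        with np.errstate(all="ignore"):
            sol = root(reduced_rhs, start, jac=reduced_jac, method="hybr")
        if sol.success and np.all(np.isfinite(sol.x)):
            x = endpoint.copy()
            x[dyn] = sol.x
            if np.max(np.abs(compiled.rhs(x)[dyn])) < tol:
                return x
        scale = np.maximum(np.abs(endpoint[dyn]), 1.0)
        start = endpoint[dyn] + rng.normal(scale=0.1 * scale)
    return None


# kept for callers that want an event-driven dense trajectory (plotting,
# period estimation); the fitness path uses `simulate`.
def simulate_dense(net: ReactionNetwork, t_end: float, n_points: int = 1000,
                   rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> Trajectory:
    compiled = compile_network(net)
    x0 = np.asarray(net.initial_concentrations, dtype=float)

    def blowup(t, x):
        return BLOWUP_LIMIT - np.max(np.abs(x))

    blowup.terminal = True
    with np.errstate(all="ignore"):
        sol = solve_ivp(
            lambda t, x: compiled.rhs(x),
            (0.0, t_end),
            x0,
            method="LSODA",
            t_eval=np.linspace(0.0, t_end, n_points),
            jac=lambda t, x: compiled.jac(x),
            rtol=rtol,
            atol=atol,
            events=blowup,
        )
    ok = sol.status == 0 and np.all(np.isfinite(sol.y))
    return Trajectory(times=sol.t, concentrations=np.clip(sol.y.T, 0.0, None), success=ok)
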