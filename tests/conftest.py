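import numpy as np
import pytest

from crnevolve.fixtures import lotka_volterra
from crnevolve.network import Reaction, ReactionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lv():
    """Unit-rate Lotka-Volterra fixture: fixed point (1, 1), eigenvalues ±i."""
    return lotka_volterra(1.0, 1.0, 1.0)


@pytest.fixture
def decay_net():
    """S0 -> S1 with k=1: the textbook exponential decay."""
    return ReactionNetwork(
        species=("S0", "S1"),
        initial_concentrations=(1.0, 0.0),
        reactions=[Reaction(("S0",), ("S1",), 1.0)],
    )


def make_net(reactions, n_species=3, concs=None):
    """Small helper: a 3-species network from (reactants, products, k[, active])."""
    species = tuple(f"S{i}" for i in range(n_species))
    if concs is None:
        concs = (1.0,) * n_species
    rs = []
    for spec in reactions:
        if len(spec) == 4:
            lhs, rhs, k, active = spec
        else:
            lhs, rhs, k = spec
            active = True
        rs.append(Reaction(tuple(lhs), tuple(rhs), k, active=active))
    return ReactionNetwork(species=species, initial_concentrations=concs, reactions=rs)
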