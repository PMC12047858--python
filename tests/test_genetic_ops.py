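"""Mutation and crossover operator contracts."""

import numpy as np
import pytest

from crnevolve.genetic_ops import (
    CrossoverConfig,
    MutationConfig,
    crossover,
    crossover_lenient,
    fitness_within_window,
    mutate,
    mutate_rate_constant,
    mutate_reaction,
)
from crnevolve.network import Reaction, random_network, reaction_key

from conftest import make_net

MCFG = MutationConfig()
XCFG = CrossoverConfig(p_crossover=0.75)


class TestRateConstantMutation:
    def test_percentage_path_stays_within_20_percent(self, rng):
        cfg = MutationConfig(redraw_probability=0.0)
        r = Reaction(("S0",), ("S1",), 10.0)
        for _ in range(2000):
            k = mutate_rate_constant(r, cfg, rng).rate_constant
            assert 8.0 <= k <= 12.0

    def test_redraw_path_uses_default_range(self, rng):
        cfg = MutationConfig(redraw_probability=1.0)
        r = Reaction(("S0",), ("S1",), 1e6)
        for _ in range(2000):
            k = mutate_rate_constant(r, cfg, rng).rate_constant
            assert 0.1 <= k <= 50.0

    def test_zero_is_a_fixed_point_of_the_percentage_path(self, rng):
        cfg = MutationConfig(redraw_probability=0.0)
        r = Reaction(("S0",), ("S1",), 0.0)
        assert mutate_rate_constant(r, cfg, rng).rate_constant == 0.0

    def test_never_negative_over_many_applications(self, rng):
        r = Reaction(("S0",), ("S1",), 0.5)
        for _ in range(5000):
            r = mutate_rate_constant(r, MCFG, rng)
            assert r.rate_constant >= 0.0


class TestReactionMutation:
    def test_deletion_preserves_the_record(self, rng):
        net = make_net([(("S0",), ("S1",), 1.0)])
        # force deletion by retrying until the branch fires
        for _ in range(100):
            out = mutate_reaction(net, MCFG, rng)
            if len(out.active_reactions()) == 0:
                assert len(out.reactions) == 1 and not out.reactions[0].active
                return
        pytest.fail("deletion branch never fired in 100 draws")

    def test_add_delete_split_is_even(self, rng):
        net = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 1.0)])
        n = 10_000
        deletions = 0
        for _ in range(n):
            out = mutate_reaction(net, MCFG, rng)
            deletions += len(out.active_reactions()) < len(net.active_reactions())
        sigma = (n * 0.25) ** 0.5
        assert abs(deletions - n / 2) < 3 * sigma

    def test_no_active_reactions_falls_back_to_addition(self, rng):
        net = make_net([(("S0",), ("S1",), 1.0, False)])
        for _ in range(50):
            out = mutate_reaction(net, MCFG, rng)
            assert len(out.active_reactions()) == 1

    def test_original_is_untouched(self, rng):
        net = make_net([(("S0",), ("S1",), 1.0)])
        before = list(net.reactions)
        for _ in range(20):
            mutate_reaction(net, MCFG, rng)
        assert net.reactions == before


class TestMutateDispatch:
    def test_rate_only_changes_exactly_one_constant(self, rng):
        cfg = MutationConfig(p_rate_mutation=1.0, p_reaction_mutation=0.0, redraw_probability=0.0)
        net = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 2.0)])
        out = mutate(net, cfg, rng)
        assert out.active_keys() == net.active_keys()
        diffs = sum(
            a.rate_constant != b.rate_constant for a, b in zip(net.reactions, out.reactions)
        )
        assert diffs == 1

    def test_topology_only_changes_active_set(self, rng):
        cfg = MutationConfig(p_rate_mutation=0.0, p_reaction_mutation=1.0)
        net = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 2.0)])
        for _ in range(30):
            out = mutate(net, cfg, rng)
            n_act, n_old = len(out.active_reactions()), len(net.active_reactions())
            merged = out.active_keys() == net.active_keys() and any(
                a.rate_constant != b.rate_constant
                for a, b in zip(net.reactions, out.reactions)
            )
            assert n_act != n_old or merged

    def test_seeded_reproducibility(self):
        net = make_net([(("S0",), ("S1",), 1.0)])
        a = mutate(net, MCFG, np.random.default_rng(7))
        b = mutate(net, MCFG, np.random.default_rng(7))
        assert a.reactions == b.reactions


class TestCrossover:
    def _parents(self, rng):
        fit = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 2.0)])
        fit.fitness = 1.0
        less = make_net([(("S0",), ("S1",), 9.0), (("S2",), ("S0",), 4.0)])
        less.fitness = 0.5
        return fit, less

    def test_offspring_topology_equals_fit_parent(self, rng):
        fit, less = self._parents(rng)
        child = crossover(fit, less, XCFG, rng)
        assert child.active_keys() == fit.active_keys()

    def test_key_only_in_less_fit_parent_is_dropped(self, rng):
        fit, less = self._parents(rng)
        child = crossover(fit, less, XCFG, rng)
        only_less = reaction_key(Reaction(("S2",), ("S0",), 4.0))
        assert only_less not in {reaction_key(r) for r in child.reactions}

    def test_shared_key_rate_comes_from_either_parent(self, rng):
        fit, less = self._parents(rng)
        shared = reaction_key(Reaction(("S0",), ("S1",), 1.0))
        seen = set()
        for _ in range(200):
            child = crossover(fit, less, XCFG, rng)
            (k,) = [r.rate_constant for r in child.reactions if reaction_key(r) == shared]
            assert k in (1.0, 9.0)
            seen.add(k)
        assert seen == {1.0, 9.0}

    def test_self_crossover_preserves_topology(self, rng):
        fit, _ = self._parents(rng)
        child = crossover(fit, fit, XCFG, rng)
        assert child.active_keys() == fit.active_keys()
        assert [r.rate_constant for r in child.reactions] == [
            r.rate_constant for r in fit.reactions
        ]

    def test_inactive_reactivation_frequency(self, rng):
        fit = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 2.0, False)])
        fit.fitness = 1.0
        n = 10_000
        reactivated = sum(
            len(crossover(fit, fit, XCFG, rng).active_reactions()) == 2 for _ in range(n)
        )
        sigma = (n * 0.25 * 0.75) ** 0.5
        assert abs(reactivated - 0.25 * n) < 3 * sigma

    def test_species_count_mismatch_rejected(self, rng):
        fit, _ = self._parents(rng)
        other = make_net([(("S0",), ("S1",), 1.0)], n_species=4, concs=(1, 1, 1, 1))
        with pytest.raises(ValueError):
            crossover(fit, other, XCFG, rng)


class TestLenientCrossover:
    def test_disjoint_parents_inherit_at_half_rate(self, rng):
        a = make_net([(("S0",), ("S1",), 1.0)])
        b = make_net([(("S1",), ("S2",), 2.0)])
        n = 10_000
        count_a = count_b = 0
        key_a, key_b = a.reactions[0].key, b.reactions[0].key
        for _ in range(n):
            child = crossover_lenient(a, b, XCFG, rng)
            keys = {reaction_key(r) for r in child.reactions}
            count_a += key_a in keys
            count_b += key_b in keys
        sigma = (n * 0.25) ** 0.5
        assert abs(count_a - n / 2) < 3 * sigma
        assert abs(count_b - n / 2) < 3 * sigma

    def test_identical_parents_give_identical_topology(self, rng):
        a = make_net([(("S0",), ("S1",), 1.0), (("S1",), ("S2",), 2.0)])
        for _ in range(50):
            child = crossover_lenient(a, a, XCFG, rng)
            assert child.active_keys() == a.active_keys()

    def test_shared_keys_always_inherited(self, rng):
        a = make_net([(("S0",), ("S1",), 1.0), (("S0",), ("S2",), 3.0)])
        b = make_net([(("S0",), ("S1",), 5.0), (("S1",), ("S2",), 2.0)])
        shared = a.reactions[0].key
        for _ in range(200):
            child = crossover_lenient(a, b, XCFG, rng)
            assert shared in {reaction_key(r) for r in child.reactions}

    def test_fitness_window(self):
        assert fitness_within_window(1.0, 0.96, 0.05)
        assert not fitness_within_window(1.0, 0.90, 0.05)
        assert fitness_within_window(0.0, 0.0, 0.05)


def test_rates_never_negative_under_operator_storm(rng):
    """Long random sequences of all operators keep every invariant."""
    nets = [random_network(rng) for _ in range(4)]
    for net in nets:
        net.fitness = float(rng.random())
    for _ in range(3000):
        op = rng.integers(4)
        i, j = rng.integers(len(nets), size=2)
        if op == 0:
            nets[i] = mutate(nets[i], MCFG, rng, ensure_change=False)
        elif op == 1:
            nets[i] = mutate_reaction(nets[i], MCFG, rng)
        elif op == 2:
            fit, less = (nets[i], nets[j]) if (nets[i].fitness or 0) >= (nets[j].fitness or 0) else (nets[j], nets[i])
            nets[i] = crossover(fit, less, XCFG, rng)
        else:
            nets[i] = crossover_lenient(nets[i], nets[j], XCFG, rng)
        nets[i].fitness = float(rng.random())
        keys = [reaction_key(r) for r in nets[i].reactions]
        assert len(keys) == len(set(keys))
        assert all(r.rate_constant >= 0 for r in nets[i].reactions)
        assert len(nets[i].species) == 3
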