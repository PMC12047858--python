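"""Reproduction machinery and the generational loop."""

import dataclasses
import json

import numpy as np
import pytest

from crnevolve.evolution import (
    EvolutionConfig,
    allocate_offspring,
    cull,
    evolve,
    next_generation,
    select_elites,
    tournament_select,
)
from crnevolve.genetic_ops import CrossoverConfig, MutationConfig
from crnevolve.speciation import SpeciesGroup

from conftest import make_net


def group_of(fitnesses, gid=0):
    members = []
    for i, f in enumerate(fitnesses):
        net = make_net([(("S0",), ("S1",), 1.0 + i)])
        net.fitness = f
        net.uid = i
        members.append(net)
    return SpeciesGroup(id=gid, representative=members[0], members=members)


class TestAllocateOffspring:
    def test_equal_fitness_equal_quota(self):
        groups = [group_of([1.0], gid=i) for i in range(4)]
        quotas = allocate_offspring(groups, population_size=100, cap=0.5)
        assert all(q == 25 for q in quotas.values())

    def test_cap_without_redistribution(self):
        groups = [group_of([9.0], gid=0), group_of([1.0], gid=1)]
        quotas = allocate_offspring(groups, population_size=100, cap=0.1)
        assert quotas == {0: 10, 1: 10}
        assert sum(quotas.values()) == 20  # surplus is simply lost

    def test_single_group_cap(self):
        quotas = allocate_offspring([group_of([2.0])], population_size=100, cap=0.1)
        assert quotas == {0: 10}

    def test_all_zero_fitness_uniform(self):
        groups = [group_of([0.0], gid=i) for i in range(5)]
        quotas = allocate_offspring(groups, population_size=50, cap=1.0)
        assert all(q == 10 for q in quotas.values())


class TestElitesAndCulling:
    def test_ten_percent_of_a_large_group(self):
        g = group_of(np.linspace(1, 0, 30))
        elites = select_elites(g, quota=30, elite_fraction=0.10)
        assert len(elites) == 3
        assert [e.fitness for e in elites] == sorted(
            (m.fitness for m in g.members), reverse=True
        )[:3]

    def test_small_group_passes_single_best(self):
        g = group_of([0.2, 0.9, 0.5, 0.1, 0.3, 0.6, 0.4])
        elites = select_elites(g, quota=7)
        assert len(elites) == 1 and elites[0].fitness == 0.9

    def test_tie_breaks_toward_lower_uid(self):
        g = group_of([0.5, 0.5, 0.5])
        (elite,) = select_elites(g, quota=3)
        assert elite.uid == 0

    def test_cull_removes_floor_fraction(self):
        g = group_of(np.linspace(1, 0, 20))
        survivors = cull(g, cull_fraction=0.10)
        assert len(survivors) == 18
        assert min(s.fitness for s in survivors) > 0

    def test_small_group_not_culled(self):
        g = group_of([0.1, 0.2, 0.3, 0.4, 0.5])
        assert len(cull(g, cull_fraction=0.10)) == 5


class TestTournament:
    def test_singleton_pool(self, rng):
        g = group_of([0.7])
        assert tournament_select(g.members, rng) is g.members[0]

    def test_rank_selection_probabilities(self, rng):
        # with n ranked members, rank r (1=worst) wins a 2-draw tournament
        # with probability (2r-1)/n^2
        g = group_of([0.1, 0.2, 0.3, 0.4])
        n = 4
        trials = 20_000
        wins = {m.uid: 0 for m in g.members}
        for _ in range(trials):
            wins[tournament_select(g.members, rng).uid] += 1
        for rank, uid in enumerate([0, 1, 2, 3], start=1):
            p = (2 * rank - 1) / n**2
            sigma = (trials * p * (1 - p)) ** 0.5
            assert abs(wins[uid] - trials * p) < 4 * sigma


class TestNextGeneration:
    CFG = EvolutionConfig(population_size=30, max_generations=5)

    def test_size_equals_quota_sum(self, rng):
        groups = [group_of(np.linspace(1, 0.5, 12), gid=i) for i in range(2)]
        quotas = {0: 8, 1: 5}
        pop = next_generation(groups, self.CFG, rng, quotas=quotas)
        assert len(pop) == 13

    def test_no_crossover_means_all_mutated(self, rng):
        g = group_of(np.linspace(1, 0.5, 12))
        pop = next_generation([g], self.CFG, rng, quotas={0: 12})

        def sig(net):
            return frozenset({(r.key, r.rate_constant, r.active) for r in net.reactions})

        originals = {sig(m) for m in g.members}
        elites = select_elites(g, 12, self.CFG.elite_fraction)
        n_unchanged = sum(sig(m) in originals for m in pop)
        assert n_unchanged == len(elites)

    def test_crossover_and_mutation_overlap_frequency(self, rng):
        # p_c = p_m = 0.75: crossover iff p < .75, mutation iff p >= .25,
        # so both happen for p in [.25,.75): probability one half
        cfg = dataclasses.replace(
            self.CFG, p_mutation=0.75, crossover=CrossoverConfig(p_crossover=0.75)
        )
        draws = 4000
        both = 0
        for _ in range(draws):
            p = rng.random()
            both += (p < 0.75) and (p >= 0.25)
        sigma = (draws * 0.25) ** 0.5
        assert abs(both - draws / 2) < 3 * sigma

    def test_invalid_probability_combination_rejected(self):
        with pytest.raises(ValueError):
            EvolutionConfig(p_mutation=0.3, crossover=CrossoverConfig(p_crossover=0.3))

    def test_single_offspring_quota_keeps_improving_mutation_only(self, rng):
        # a species allocated one offspring gives its best a trial
        # mutation, kept only when the (mocked) evaluation improves on it
        g = group_of([0.4, 0.6])
        best_sig = {(r.key, r.rate_constant, r.active) for r in g.best().reactions}

        (worse,) = next_generation([g], self.CFG, rng, quotas={0: 1},
                                   evaluate=lambda net: 0.1)
        assert {(r.key, r.rate_constant, r.active) for r in worse.reactions} == best_sig
        assert worse.fitness == 0.6

        (better,) = next_generation([g], self.CFG, rng, quotas={0: 1},
                                    evaluate=lambda net: 0.9)
        assert {(r.key, r.rate_constant, r.active) for r in better.reactions} != best_sig
        assert better.fitness == 0.9


class TestEvolve:
    SMALL = EvolutionConfig(
        population_size=20,
        max_generations=8,
        n_reactions=3,
        seed=99,
    )

    def test_same_seed_identical_outputs(self, tmp_path):
        a = evolve(self.SMALL, out_dir=tmp_path / "a")
        b = evolve(self.SMALL, out_dir=tmp_path / "b")
        assert [dataclasses.asdict(r) for r in a.records] == [
            dataclasses.asdict(r) for r in b.records
        ]
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_settings_json_reproduces_the_trial(self, tmp_path):
        a = evolve(self.SMALL, out_dir=tmp_path / "a")
        cfg = EvolutionConfig.from_json(tmp_path / "a" / "settings.json")
        b = evolve(cfg)
        assert [r.best_fitness for r in a.records] == [r.best_fitness for r in b.records]

    def test_early_stop_on_fitness(self):
        cfg = dataclasses.replace(self.SMALL, fitness_stop=1e-6, max_generations=50)
        res = evolve(cfg)
        assert res.stopped_early and len(res.records) == 1

    def test_best_fitness_non_decreasing_with_elitism(self):
        cfg = dataclasses.replace(self.SMALL, max_generations=15, fitness_stop=1e9)
        res = evolve(cfg)
        bests = [r.best_fitness for r in res.records]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bests, bests[1:]))

    def test_population_size_stays_bounded(self):
        cfg = dataclasses.replace(self.SMALL, max_generations=12, fitness_stop=1e9)
        res = evolve(cfg)
        for r in res.records:
            assert r.population_size <= cfg.population_size + r.species_count

    def test_written_models_carry_fitness(self, tmp_path):
        evolve(self.SMALL, out_dir=tmp_path)
        ants = list(tmp_path.glob("species_*_best.ant"))
        assert ants
        assert all("# fitness:" in f.read_text() for f in ants)

    def test_config_json_round_trip(self, tmp_path):
        cfg = dataclasses.replace(
            self.SMALL,
            mutation=MutationConfig(percent_range=0.3),
            crossover=CrossoverConfig(p_crossover=0.5, lenient_enabled=True),
            p_mutation=0.5,
        )
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert EvolutionConfig.from_json(path) == cfg
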