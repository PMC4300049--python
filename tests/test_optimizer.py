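"""Evolutionary search: population construction, operators, fitness, selection."""

import math

import numpy as np
import pandas as pd
import pytest

from lcrgene.assembly import build_fragments
from lcrgene.codon import CODON_TO_AA, load_usage_table, translate, uniform_usage_table
from lcrgene.optimizer import (
    EAConfig,
    _mutate_codon,
    evaluate_fitness,
    fitness_from_components,
    hill_climb,
    init_population,
    mutate,
    run_ea,
    select,
)
from lcrgene.thermo import EnergyModel

AAS = "ARNDCQEGHILKMFPSTWYV"


def random_peptide(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


def usage_from_counts(counts):
    full = {c: 1 for c in CODON_TO_AA}
    full.update(counts)
    return load_usage_table(pd.DataFrame(
        {"codon": list(full), "amino_acid": [CODON_TO_AA[c] for c in full],
         "count": list(full.values())}
    ))


class TestInitPopulation:
    def test_individuals_valid_and_encode_peptide(self, rng):
        peptide = random_peptide(rng, 30)
        config = EAConfig(population_size=10, seed=1)
        pop = init_population(peptide, uniform_usage_table(), config)
        assert len(pop.individuals) == 10
        for d in pop.individuals:
            d.validate(config.constraints)
            assert translate(d.dna) == peptide

    def test_same_seed_same_population(self, rng):
        peptide = random_peptide(rng, 25)
        config = EAConfig(population_size=8, seed=42)
        a = init_population(peptide, uniform_usage_table(), config)
        b = init_population(peptide, uniform_usage_table(), config)
        assert a.individuals == b.individuals

    def test_main_chain_counts_span_feasible_range(self, rng):
        # 30 aa -> 93 nt with stop; lengths in [20, 80] admit k in {2, 3, 4}
        peptide = random_peptide(rng, 30)
        config = EAConfig(population_size=40, seed=3)
        seen = set()
        for seed in range(8):
            pop = init_population(peptide, uniform_usage_table(),
                                  EAConfig(population_size=40, seed=seed))
            for d in pop.individuals:
                d.validate(config.constraints)
                seen.add(d.k)
        assert seen == {2, 3, 4}

    def test_infeasible_constraints_rejected(self):
        with pytest.raises(Exception, match="no fragmentation|helper"):
            init_population("MW", uniform_usage_table(),
                            EAConfig(population_size=4, seed=0))


class TestMutate:
    def test_child_differs_in_at_most_one_aspect(self, rng):
        peptide = random_peptide(rng, 40)
        config = EAConfig(population_size=2, seed=9)
        parent = init_population(peptide, uniform_usage_table(), config).individuals[0]
        for _ in range(200):
            child = mutate(parent, config, rng)
            child.validate(config.constraints)
            assert translate(child.dna) == peptide
            aspects = 0
            if child.dna != parent.dna:
                aspects += 1
                diff_codons = sum(
                    child.dna[i:i + 3] != parent.dna[i:i + 3]
                    for i in range(0, len(parent.dna), 3)
                )
                assert diff_codons == 1
            if child.cuts != parent.cuts:
                aspects += 1
                assert sum(a != b for a, b in zip(child.cuts, parent.cuts)) == 1
            if child.helpers != parent.helpers:
                aspects += 1
                assert sum(a != b for a, b in
                           zip(child.helpers, parent.helpers)) == 1
            assert aspects <= 1

    def test_codon_operator_degenerate_on_met_trp(self, rng):
        from lcrgene.assembly import GeneDesign

        design = GeneDesign("ATGTGG" * 5 + "ATGTGGATG", (), ())
        config = EAConfig(population_size=2, seed=0, stop_codon=None,
                          l_min=20, l_max=80)
        for _ in range(50):
            assert _mutate_codon(design, config, rng).dna == design.dna

    def test_cut_shift_never_violates_bounds(self, rng):
        peptide = random_peptide(rng, 27)  # 84 nt: k = 2..4
        config = EAConfig(population_size=2, seed=5)
        parent = init_population(peptide, uniform_usage_table(), config).individuals[0]
        for _ in range(1000):
            child = mutate(parent, config, rng)
            child.validate(config.constraints)  # raises on any violation


class TestFitnessArithmetic:
    def test_upper_bound_at_zero_components(self):
        fb = fitness_from_components(0.0, 120, 120, 1, 1, EAConfig())
        assert fb.fitness == pytest.approx(1.0)
        assert fb.f_n == 0.0 and fb.f_s == 0.0

    def test_composite_is_reciprocal_sum(self):
        # F_C=0.1, F_N=0.2, F_S=0 -> F = 1/1.3
        config = EAConfig(w_n=1.0)
        # N chosen so (N - N_min)/(N_max - N_min) = 0.2
        fb = fitness_from_components(0.1, 136, 100, 2, 1, config)
        assert fb.f_n == pytest.approx(0.2)
        assert fb.fitness == pytest.approx(1 / 1.3)

    @pytest.mark.parametrize("s,expected", [(1, 0.0), (3, 4.0)])
    def test_protocol_penalty_is_squared(self, s, expected):
        fb = fitness_from_components(0.0, 150, 100, 2, s, EAConfig(w_s=1.0))
        assert fb.f_s == pytest.approx(expected)

    def test_nucleotide_cost_plug_in(self):
        # N_main=100, k=2, L_min=20: N_min=120, N_max=200; N=160 -> 0.5
        fb = fitness_from_components(0.0, 160, 100, 2, 1, EAConfig(w_n=1.0))
        assert fb.n_min == 120 and fb.n_max == 200
        assert fb.f_n == pytest.approx(0.5)

    def test_fitness_in_unit_interval_and_monotone(self):
        base = fitness_from_components(0.3, 160, 100, 2, 2, EAConfig())
        worse = fitness_from_components(0.4, 160, 100, 2, 2, EAConfig())
        assert 0 < worse.fitness < base.fitness <= 1


class TestSelect:
    def test_proportional_frequency_matches_fitness(self):
        rng = np.random.default_rng(0)
        config = EAConfig(selection="proportional")
        picks = select([0.9, 0.1], 10000, config, rng)
        hits = picks.count(0)
        sigma = math.sqrt(10000 * 0.9 * 0.1)
        assert abs(hits - 9000) < 5 * sigma

    def test_ranking_invariant_under_monotone_transform(self):
        config = EAConfig(selection="ranking")
        f = [0.2, 0.9, 0.5, 0.7]
        a = select(f, 50, config, np.random.default_rng(4))
        b = select([x**3 for x in f], 50, config, np.random.default_rng(4))
        assert a == b

    def test_tournament_worse_needs_double_draw(self):
        rng = np.random.default_rng(2)
        config = EAConfig(selection="tournament")
        picks = select([1.0, 0.5], 10000, config, rng)
        # the worse individual wins only when sampled twice: P = 1/4
        frac = picks.count(1) / 10000
        assert abs(frac - 0.25) < 5 * math.sqrt(0.25 * 0.75 / 10000)

    def test_all_zero_proportional_falls_back_to_uniform(self):
        rng = np.random.default_rng(3)
        picks = select([0.0, 0.0, 0.0], 300,
                       EAConfig(selection="proportional"), rng)
        assert set(picks) == {0, 1, 2}


class TestHillClimb:
    def test_single_off_target_codon_is_fixed(self, model):
        # Thr encoded ACC everywhere except one ACA; the table requires ACC
        # only, and the A/C-only sequence is thermodynamically inert, so the
        # exact fix is in the neighborhood and F_C reaches 0
        table = usage_from_counts({"ACC": 100, "ACA": 0, "ACG": 0, "ACT": 0})
        from lcrgene.assembly import GeneDesign

        config = EAConfig(population_size=2, seed=0, l_min=20, l_max=80)
        design = GeneDesign("ACC" * 4 + "ACA" + "ACC" * 5 + "TAA", (), ())
        start = evaluate_fitness(design, table, config, model)
        assert start.f_c > 0
        improved, fit = hill_climb(design, table, config, model)
        assert fit.f_c == pytest.approx(0.0)
        assert fit.fitness >= start.fitness

    def test_local_optimum_is_fixed_point(self, model):
        table = usage_from_counts({"ACC": 100, "ACA": 0, "ACG": 0, "ACT": 0})
        from lcrgene.assembly import GeneDesign

        config = EAConfig(population_size=2, seed=0)
        design = GeneDesign("ACC" * 10 + "TAA", (), ())
        improved, fit = hill_climb(design, table, config, model)
        assert improved == design

    def test_never_worsens_random_designs(self, model, rng):
        config = EAConfig(population_size=5, seed=8, generations=0,
                          hill_climb_max_rounds=2)
        peptide = random_peptide(rng, 15)
        table = uniform_usage_table()
        pop = init_population(peptide, table, config)
        for design in pop.individuals[:3]:
            before = evaluate_fitness(design, table, config, model)
            _, after = hill_climb(design, table, config, model)
            assert after.fitness >= before.fitness


class TestRunEA:
    def test_seeded_run_reproducible(self, model):
        config = EAConfig(population_size=6, generations=3, seed=17,
                          hill_climb_final=False)
        table = uniform_usage_table()
        peptide = "MTHKQPLIVENDS"  # 13 aa -> 42 nt
        r1 = run_ea(peptide, table, config, EnergyModel(model.params))
        r2 = run_ea(peptide, table, config, EnergyModel(model.params))
        assert r1[0] == r2[0]
        assert r1[1] == r2[1]

    def test_best_f_non_decreasing(self, model):
        config = EAConfig(population_size=6, generations=5, seed=11,
                          hill_climb_final=False)
        peptide = "MTHKQPLIVENDSAR"
        _, _, _, stats = run_ea(peptide, uniform_usage_table(), config, model)
        best = [s.best_f for s in stats]
        assert best == sorted(best)

    def test_single_codon_amino_acids_reach_zero_deviation(self, model):
        config = EAConfig(population_size=4, generations=2, seed=2,
                          hill_climb_final=False)
        peptide = "MW" * 8  # Met and Trp have one codon each
        _, fit, _, _ = run_ea(peptide, uniform_usage_table(), config, model)
        assert fit.f_c == pytest.approx(0.0)


class TestEnergyCache:
    def test_fitness_identical_with_and_without_cache(self, params, rng):
        config = EAConfig(population_size=10, seed=13)
        peptide = random_peptide(rng, 25)
        table = uniform_usage_table()
        pop = init_population(peptide, table, config)
        cached = EnergyModel(params, cache=True)
        for design in pop.individuals:
            a = evaluate_fitness(design, table, config, cached)
            b = evaluate_fitness(design, table, config,
                                 EnergyModel(params, cache=False))
            assert a == b

    def test_mutation_refolds_at_most_three_fragments_worth(self, params, rng):
        config = EAConfig(population_size=2, seed=21)
        peptide = random_peptide(rng, 30)
        table = uniform_usage_table()
        parent = init_population(peptide, table, config).individuals[0]
        model = EnergyModel(params, cache=True)
        evaluate_fitness(parent, table, config, model)
        n_frags = len(build_fragments(parent, config.constraints))
        for _ in range(20):
            child = mutate(parent, config, rng)
            before = model.cache_misses
            evaluate_fitness(child, table, config, model)
            # a mutation touches <= 3 oligos, so at most 3 * n_frags pairs
            # need fresh folds
            assert model.cache_misses - before <= 3 * n_frags
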