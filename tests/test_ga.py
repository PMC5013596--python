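"""Evolutionary loop: operators, statistics, caching, oracle equivalence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gamerge as gm
from gamerge.ga import (
    GAParams,
    GroupEvaluator,
    canonical_form,
    init_population,
    tournament_select,
    uniform_crossover,
    uniform_mutation,
)
from tests.conftest import jaccard


class TestInitPopulation:
    def test_single_group_all_ones(self):
        pop = init_population(9, GAParams(n_groups=1), np.random.default_rng(0))
        assert all((c == 1).all() for c in pop)

    def test_deterministic_under_seed(self):
        a = init_population(9, GAParams(), np.random.default_rng(5))
        b = init_population(9, GAParams(), np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_gene_frequencies_uniform(self):
        pop = init_population(10_000, GAParams(population_size=2, n_groups=3), np.random.default_rng(1))
        genes = pop[0]
        for g in (1, 2, 3):
            freq = np.mean(genes == g)
            sigma = np.sqrt((1 / 3) * (2 / 3) / 10_000)
            assert abs(freq - 1 / 3) < 3 * sigma


class TestCrossover:
    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(0)
        a, b = np.array([1, 2, 3, 1]), np.array([3, 1, 2, 2])
        c1, c2 = uniform_crossover(a, b, 0.0, rng)
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, b)

    def test_probability_one_swaps_parents(self):
        rng = np.random.default_rng(0)
        a, b = np.array([1, 2, 3, 1]), np.array([3, 1, 2, 2])
        c1, c2 = uniform_crossover(a, b, 1.0, rng)
        np.testing.assert_array_equal(c1, b)
        np.testing.assert_array_equal(c2, a)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(0, 1))
    def test_positionwise_conservation(self, seed, p):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 4, size=20)
        b = rng.integers(1, 4, size=20)
        c1, c2 = uniform_crossover(a, b, p, rng)
        for i in range(20):
            assert {c1[i], c2[i]} == {a[i], b[i]}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            uniform_crossover(np.ones(3, int), np.ones(4, int), 0.5, np.random.default_rng(0))


class TestMutation:
    def test_zero_probability_is_identity(self):
        c = np.array([1, 2, 3])
        out = uniform_mutation(c, 0.0, 3, np.random.default_rng(0))
        np.testing.assert_array_equal(out, c)

    def test_single_group_is_identity(self):
        c = np.ones(50, dtype=int)
        out = uniform_mutation(c, 1.0, 1, np.random.default_rng(0))
        np.testing.assert_array_equal(out, c)

    def test_changed_fraction_matches_expectation(self):
        """Resampling flips a gene with rate p * (1 - 1/g)."""
        p, g, n = 0.05, 3, 100_000
        rng = np.random.default_rng(2)
        c = rng.integers(1, g + 1, size=n)
        out = uniform_mutation(c, p, g, rng)
        expect = p * (1 - 1 / g)
        observed = np.mean(out != c)
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(observed - expect) < 3 * sigma


class TestTournament:
    def test_single_individual(self):
        pop = [np.array([1, 2])]
        out = tournament_select(pop, [5.0], 3, np.random.default_rng(0))
        np.testing.assert_array_equal(out, pop[0])

    def test_selection_pressure_rate(self):
        """P(best of 3 distinct fitnesses selected) = 1 - (2/3)^3."""
        pop = [np.array([i]) for i in range(3)]
        fits = [1.0, 2.0, 3.0]
        rng = np.random.default_rng(3)
        n = 10_000
        wins = sum(tournament_select(pop, fits, 3, rng)[0] == 2 for _ in range(n))
        expect = 1 - (2 / 3) ** 3
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(wins / n - expect) < 3 * sigma


class TestCanonicalForm:
    def test_relabels_by_first_appearance(self):
        np.testing.assert_array_equal(canonical_form(np.array([3, 3, 1, 2])), [1, 1, 2, 3])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_label_permutations_collapse(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(1, 4, size=12)
        perm = rng.permutation([1, 2, 3])
        relabeled = np.array([perm[x - 1] for x in c])
        np.testing.assert_array_equal(canonical_form(c), canonical_form(relabeled))


@pytest.fixture(scope="module")
def small_evaluator():
    cfg = gm.SynthConfig(
        n_subsets=8,
        group_spec=((5, 0.0), (3, 0.7)),
        completeness_per_subset=0.3,
        seed=21,
    )
    pool, truth = gm.generate_pool(cfg)
    ev = GroupEvaluator(pool, gm.FitnessWeights(), gm.make_shells(36.0, 2.0, 10), seed=21)
    return pool, truth, ev


class TestEvaluator:
    def test_fitness_invariant_to_label_permutation(self, small_evaluator):
        pool, _, ev = small_evaluator
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(1, 4, size=len(pool))
            perm = rng.permutation([1, 2, 3])
            relabeled = np.array([perm[x - 1] for x in c])
            assert ev(c) == pytest.approx(ev(relabeled), rel=1e-12)

    def test_cache_hits_on_symmetric_chromosomes(self, small_evaluator):
        pool, _, ev = small_evaluator
        before = ev.n_evaluations
        c = np.array([1, 1, 2, 2, 1, 3, 3, 1])
        ev(c)
        mid = ev.n_evaluations
        ev(np.array([2, 2, 3, 3, 2, 1, 1, 2]))  # same partition, new labels
        assert ev.n_evaluations == mid
        assert mid >= before


class TestEvolve:
    def test_zero_generations_reports_initial_population(self, small_evaluator):
        pool, _, ev = small_evaluator
        rec = gm.evolve(pool, GAParams(population_size=6, generations=0, seed=1), ev)
        assert len(rec.generations) == 1
        assert rec.best_fitness == rec.generations[0].best

    def test_deterministic_run_records(self, small_evaluator):
        pool, truth, _ = small_evaluator
        scheme = gm.make_shells(36.0, 2.0, 10)
        params = GAParams(population_size=8, generations=10, seed=9)
        recs = []
        for _ in range(2):
            ev = GroupEvaluator(pool, gm.FitnessWeights(), scheme, seed=21)
            recs.append(gm.evolve(pool, params, ev))
        a, b = recs
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.best_chromosome, b.best_chromosome)
        assert [g.best for g in a.generations] == [g.best for g in b.generations]
        assert [g.mean for g in a.generations] == [g.mean for g in b.generations]

    def test_best_ever_fitness_monotone(self, small_evaluator):
        pool, _, ev = small_evaluator
        rec = gm.evolve(pool, GAParams(population_size=10, generations=25, seed=2), ev)
        trace = rec.best_ever_trace
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_failing_evaluator_gives_sentinel(self, small_evaluator):
        pool, _, _ = small_evaluator

        def broken(c):
            raise RuntimeError("boom")

        rec = gm.evolve(pool, GAParams(population_size=4, generations=2, seed=0), broken)
        assert rec.best_fitness == gm.fitness.MIN_FITNESS


class TestOracleEquivalence:
    def test_ga_attains_exhaustive_maximum(self, small_evaluator):
        """g=2 on 8 subsets: GA matches brute-force enumeration of all 2^8
        assignments in at least 4 of 5 seeds."""
        pool, _, _ = small_evaluator
        scheme = gm.make_shells(36.0, 2.0, 10)
        ev = GroupEvaluator(pool, gm.FitnessWeights(), scheme, seed=21)
        oracle_best = max(
            ev(np.array(genes)) for genes in itertools.product((1, 2), repeat=len(pool))
        )
        hits = 0
        for seed in range(5):
            ev_run = GroupEvaluator(pool, gm.FitnessWeights(), scheme, seed=21)
            params = GAParams(population_size=20, generations=100, n_groups=2, seed=seed)
            rec = gm.evolve(pool, params, ev_run)
            if rec.best_fitness == pytest.approx(oracle_best, rel=1e-12):
                hits += 1
        assert hits >= 4
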