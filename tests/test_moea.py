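"""NSGA-II components, the evolutionary loop and the brute-force oracle."""

import numpy as np
import pytest

from paretomut import (
    COVERAGE_OVERLAP,
    COVERAGE_SIZE,
    AlgorithmParams,
    ConfigurationError,
    GeneSelection,
    ObjectiveVector,
    ParetoSet,
    SimpleSetup,
    crowding_distance,
    dominates,
    evolve,
    nondominated_sort,
    pareto_front_exact,
    scheduled_evaluations,
    simple_to_algorithm_params,
)
from paretomut.moea import (
    brute_force_entries,
    crossover,
    initialize_population,
    mutate,
    tournament_select,
)
from .conftest import random_matrix


def _small_params(**overrides):
    defaults = dict(mu=8, p_cx=0.2, p_sel=0.3, p_mut=0.2, tau=3, k=50, seed=1)
    defaults.update(overrides)
    return AlgorithmParams(**defaults)


class TestParameterMapping:
    def test_use_case_setup_maps_to_reference_probabilities(self):
        params = simple_to_algorithm_params(SimpleSetup(), n_genes=208)
        assert params.mu == 100
        assert round(params.p_sel, 4) == 0.0962
        assert round(params.p_mut, 4) == 0.0096
        assert params.p_cx == pytest.approx(0.1)
        assert params.tau == 10
        assert params.k == 1_000_000

    def test_zero_swapped_genes_gives_zero_mutation(self):
        setup = SimpleSetup(swapped_genes=0)
        assert simple_to_algorithm_params(setup, 50).p_mut == 0.0

    def test_rejects_empty_pool_and_overflowing_probability(self):
        with pytest.raises(ConfigurationError):
            simple_to_algorithm_params(SimpleSetup(), n_genes=0)
        with pytest.raises(ConfigurationError, match="p_sel"):
            simple_to_algorithm_params(SimpleSetup(initially_selected_genes=30),
                                       n_genes=10)

    def test_invalid_setup_and_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SimpleSetup(population_size=7)
        with pytest.raises(ConfigurationError):
            AlgorithmParams(mu=4, p_cx=1.5, p_sel=0, p_mut=0, tau=2, k=1)
        with pytest.raises(ConfigurationError):
            AlgorithmParams(mu=4, p_cx=0.1, p_sel=0, p_mut=0, tau=5, k=1)

    def test_scheduled_budget_identity(self):
        params = simple_to_algorithm_params(SimpleSetup(), n_genes=208)
        assert scheduled_evaluations(params) == 10 ** 8


class TestVariationOperators:
    def test_initial_selection_size_matches_inclusion_probability(self):
        genes = [f"g{i:03d}" for i in range(208)]
        params = AlgorithmParams(mu=1000, p_cx=0.1, p_sel=20 / 208,
                                 p_mut=0.01, tau=2, k=1, seed=7)
        pop = initialize_population(params, genes, np.random.default_rng(7))
        mean_size = np.mean([len(sel) for sel in pop])
        assert mean_size == pytest.approx(20, abs=1.5)

    def test_initialization_extremes(self):
        genes = ["a", "b", "c"]
        rng = np.random.default_rng(0)
        empty = initialize_population(_small_params(p_sel=0.0), genes, rng)
        assert all(len(s) == 0 for s in empty)
        full = initialize_population(_small_params(p_sel=1.0), genes, rng)
        assert all(s.members == ("a", "b", "c") for s in full)

    def test_mutation_extremes_and_expected_flip_count(self):
        genes = [f"g{i:03d}" for i in range(208)]
        sel = GeneSelection(genes[:20])
        rng = np.random.default_rng(3)
        assert mutate(sel, genes, 0.0, rng) == sel
        complement = mutate(sel, genes, 1.0, rng)
        assert set(complement.members) == set(genes) - set(sel.members)
        flips = []
        for _ in range(10_000):
            child = mutate(sel, genes, 2 / 208, rng)
            flips.append(len(set(child.members) ^ set(sel.members)))
        assert np.mean(flips) == pytest.approx(2.0, abs=0.05)

    def test_crossover_copies_identity_and_conservation(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(5)
        a = GeneSelection(genes[:5])
        b = GeneSelection(genes[3:9])
        ca, cb = crossover(a, b, genes, 0.0, rng)
        assert (ca, cb) == (a, b)
        same, same2 = crossover(a, a, genes, 1.0, rng)
        assert same == a and same2 == a
        for _ in range(50):
            ca, cb = crossover(a, b, genes, 1.0, rng)
            for g in genes:
                assert (g in ca) + (g in cb) == (g in a) + (g in b)

    def test_crossover_rejects_foreign_genes(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            crossover(GeneSelection(["x"]), GeneSelection(["a"]),
                      ["a", "b"], 1.0, rng)


class TestSelection:
    def test_strong_pressure_picks_the_better_rank(self):
        population = [GeneSelection(["a"]), GeneSelection(["b"])]
        ranks, crowd = [1, 2], [np.inf, np.inf]
        rng = np.random.default_rng(11)
        n = 100_000
        wins = sum(
            tournament_select(population, ranks, crowd, 10, rng) == population[0]
            for _ in range(n)
        )
        # true probability 1 - 2^-10 ~ 0.99902; bound is >15 SD below it
        assert wins / n >= 0.9985

    def test_tau_one_is_uniform_draw(self):
        population = [GeneSelection([g]) for g in "abcd"]
        rng = np.random.default_rng(2)
        picks = {tournament_select(population, [1] * 4, [0.0] * 4, 1, rng).members
                 for _ in range(200)}
        assert len(picks) == 4

    def test_empty_population_rejected(self):
        with pytest.raises(ConfigurationError):
            tournament_select([], [], [], 2, np.random.default_rng(0))


class TestNondominatedSortAndCrowding:
    def _vecs(self, pairs, mode=COVERAGE_OVERLAP):
        return [ObjectiveVector(c, s, mode) for c, s in pairs]

    def test_hand_checked_partition(self):
        fronts = nondominated_sort(self._vecs([(3, 1), (3, 2), (2, 0)]))
        assert fronts == [[0, 2], [1]]

    def test_identical_vectors_share_one_front(self):
        fronts = nondominated_sort(self._vecs([(2, 1)] * 4))
        assert fronts == [[0, 1, 2, 3]]

    def test_trade_off_chain_is_one_front(self):
        fronts = nondominated_sort(self._vecs([(1, 0), (2, 1), (3, 2)]))
        assert fronts == [[0, 1, 2]]

    def test_mixed_modes_rejected(self):
        vecs = [ObjectiveVector(1, 0, COVERAGE_OVERLAP),
                ObjectiveVector(1, 0, COVERAGE_SIZE)]
        with pytest.raises(ConfigurationError):
            nondominated_sort(vecs)

    def test_crowding_boundaries_and_interior(self):
        assert crowding_distance(self._vecs([(1, 1)])) [0] == np.inf
        two = crowding_distance(self._vecs([(1, 2), (2, 1)]))
        assert np.isinf(two).all()
        three = crowding_distance(self._vecs([(1, 3), (2, 2), (3, 1)]))
        assert np.isinf(three[0]) and np.isinf(three[2])
        assert three[1] == pytest.approx(2.0)

    def test_crowding_permutation_invariant(self):
        vecs = self._vecs([(1, 5), (4, 2), (2, 4), (6, 1)])
        base = crowding_distance(vecs)
        perm = [2, 0, 3, 1]
        permuted = crowding_distance([vecs[i] for i in perm])
        assert np.allclose([base[i] for i in perm], permuted)

    def test_dominates_relation(self):
        a = ObjectiveVector(3, 1, COVERAGE_OVERLAP)
        b = ObjectiveVector(3, 2, COVERAGE_OVERLAP)
        assert dominates(a, b) and not dominates(b, a) and not dominates(a, a)


class TestEvolve:
    def test_single_gene_solution_space(self, toy_matrix):
        ps = evolve(toy_matrix, ["g1"], COVERAGE_SIZE, _small_params())
        assert set(ps.vectors()) <= {(0, 0), (2, 1)}

    @pytest.mark.parametrize("mode", [COVERAGE_OVERLAP, COVERAGE_SIZE])
    def test_matches_exact_oracle_on_toy(self, toy_matrix, mode):
        ps = evolve(toy_matrix, toy_matrix.gene_ids, mode, _small_params())
        exact = pareto_front_exact(toy_matrix, mode=mode)
        assert ps.vectors() == exact.vectors()
        assert ps.selections() == exact.selections()

    def test_seed_determinism(self, toy_matrix):
        a = evolve(toy_matrix, toy_matrix.gene_ids, COVERAGE_SIZE, _small_params())
        b = evolve(toy_matrix, toy_matrix.gene_ids, COVERAGE_SIZE, _small_params())
        assert a == b

    def test_evaluation_counter_accounting(self, toy_matrix):
        params = _small_params(mu=10, k=17)
        seen = []
        ps = evolve(toy_matrix, toy_matrix.gene_ids, COVERAGE_SIZE, params,
                    progress_callback=lambda it, n: seen.append((it, n)))
        assert ps.n_evaluations == 10 * 17
        assert ps.n_initial_evaluations == 10
        assert seen[0] == (1, 10) and seen[-1] == (17, 170)

    def test_result_is_internally_nondominated_and_sorted(self):
        rng = np.random.default_rng(42)
        matrix = random_matrix(rng, n_samples=20, n_genes=8)
        ps = evolve(matrix, matrix.gene_ids, COVERAGE_OVERLAP,
                    _small_params(mu=20, k=100))
        vecs = ps.vectors()
        assert vecs == sorted(vecs)
        assert len(set(vecs)) == len(vecs)
        for _, a in ps.entries:
            assert not any(dominates(b, a) for _, b in ps.entries if b != a)

    def test_empty_candidate_pool_rejected(self, toy_matrix):
        with pytest.raises(ConfigurationError):
            evolve(toy_matrix, [], COVERAGE_SIZE, _small_params())


class TestExactOracle:
    def test_refuses_large_instances(self):
        rng = np.random.default_rng(0)
        matrix = random_matrix(rng, n_samples=5, n_genes=9)
        with pytest.raises(ConfigurationError, match="refused"):
            pareto_front_exact(matrix, max_genes=8)

    def test_empty_pool_yields_empty_selection_only(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, candidate_genes=[],
                                mode=COVERAGE_SIZE)
        assert ps.vectors() == [(0, 0)]
        assert ps.selections() == [GeneSelection()]

    @pytest.mark.parametrize("mode", [COVERAGE_OVERLAP, COVERAGE_SIZE])
    def test_every_entry_nondominated_against_full_enumeration(self, mode):
        rng = np.random.default_rng(9)
        matrix = random_matrix(rng, n_samples=12, n_genes=6)
        ps = pareto_front_exact(matrix, mode=mode)
        everything = brute_force_entries(matrix, matrix.gene_ids, mode)
        for _, vec in ps.entries:
            assert not any(dominates(other, vec) for _, other in everything)
        # and every non-dominated vector is present
        nd = {v.as_tuple() for _, v in everything
              if not any(dominates(o, v) for _, o in everything)}
        assert set(ps.vectors()) == nd


class TestParetoSetContainer:
    def test_from_candidates_dedups_to_lexicographically_smallest(self, toy_matrix):
        mode = COVERAGE_OVERLAP
        entries = brute_force_entries(toy_matrix, toy_matrix.gene_ids, mode)
        ps = ParetoSet.from_candidates(entries, mode)
        assert ps.vectors() == [(3, 0), (4, 1)]
        assert ps.selections()[0].members == ("g1", "g3")

    def test_max_coverage_within_size_selector(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, mode=COVERAGE_SIZE)
        sel, vec = ps.max_coverage_within_size(2)
        assert vec.as_tuple() == (3, 2)
        sel0, vec0 = ps.max_coverage_within_size(0)
        assert sel0 == GeneSelection() and vec0.coverage == 0
        _, best = ps.max_coverage_within_size(99)
        assert best.coverage == 4
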