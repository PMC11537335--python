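"""Generational-loop operators: initialization, selection, crossover,
mutation, elitism, termination, end-to-end behaviour."""

import numpy as np
import pytest

from locusga.config import GAConfig
from locusga.estimator import LocusAssignmentModel
from locusga.ga import (
    Population,
    _crossover_masks,
    apply_elitism,
    check_termination,
    crossover,
    init_population,
    mutate,
    mutate_population,
    rank_and_group,
    run,
    select_pairs,
    termination_generation,
)
from locusga.objectives import ProposalScorer
from locusga.simulate import ScenarioParams, generate_scenario

from conftest import small_config


@pytest.fixture(scope="module")
def scored_population(small_scenario):
    config = small_config()
    scorer = ProposalScorer(small_scenario.bundle, config)
    rng = np.random.default_rng(0)
    pop = init_population(small_scenario.bundle.loci, small_scenario.bundle.catalog, config, rng, scorer)
    pop.score()
    return pop, config, scorer


class TestInit:
    def test_population_size_and_determinism(self, small_scenario):
        config = small_config()
        scorer = ProposalScorer(small_scenario.bundle, config)
        pops = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            pops.append(init_population(small_scenario.bundle.loci, small_scenario.bundle.catalog, config, rng, scorer))
        assert len(pops[0]) == config.population_size
        assert np.array_equal(pops[0].K, pops[1].K)
        assert np.array_equal(pops[0].C, pops[1].C)

    def test_single_candidate_locus_forced(self):
        sc = generate_scenario(ScenarioParams(n_loci=3, genes_per_locus=2, n_cell_types=3), seed=2)
        # shrink one locus to a single candidate
        sc.bundle.loci[0].candidate_genes = sc.bundle.loci[0].candidate_genes[:1]
        config = small_config()
        scorer = ProposalScorer(sc.bundle, config)
        pop = init_population(sc.bundle.loci, sc.bundle.catalog, config, np.random.default_rng(0), scorer)
        assert (pop.K[:, 0] == 0).all()

    def test_gene_draw_is_uniform_over_candidates(self, small_scenario):
        config = small_config()
        scorer = ProposalScorer(small_scenario.bundle, config)
        rng = np.random.default_rng(7)
        counts = np.zeros(scorer.n_cand[0])
        for _ in range(50):
            pop = init_population(small_scenario.bundle.loci, small_scenario.bundle.catalog, config, rng, scorer)
            counts += np.bincount(pop.K[:, 0], minlength=scorer.n_cand[0])
        n = counts.sum()
        p = 1 / scorer.n_cand[0]
        se = np.sqrt(p * (1 - p) * n)
        assert np.all(np.abs(counts - n * p) < 5 * se)


class TestRankAndGroup:
    def test_groups_are_equal_and_sorted(self, scored_population):
        pop, config, _ = scored_population
        ranked, groups = rank_and_group(pop, np.random.default_rng(1), config)
        assert len(groups) == config.n_groups
        assert all(len(g) == len(pop) // config.n_groups for g in groups)
        assert np.all(np.diff(ranked.fitness) <= 0)
        assert ranked.fitness[0] == pop.fitness.max()

    def test_degenerate_ties_still_partition(self, scored_population):
        pop, config, scorer = scored_population
        flat = Population(K=pop.K.copy(), C=pop.C.copy(), scorer=scorer,
                          fitness=np.zeros(len(pop)), fractions=np.zeros((len(pop), 11)))
        ranked, groups = rank_and_group(flat, np.random.default_rng(2), config)
        assert sum(len(g) for g in groups) == len(pop)
        # tie-break is a seeded permutation: two seeds give different orders
        ranked2, _ = rank_and_group(flat, np.random.default_rng(3), config)
        assert not np.array_equal(ranked.K, ranked2.K)


class TestSelection:
    def test_pairs_are_distinct_parents(self, scored_population):
        pop, config, _ = scored_population
        _, groups = rank_and_group(pop, np.random.default_rng(1), config)
        pairs, drawn_groups = select_pairs(groups, config, np.random.default_rng(5))
        flat = [i for p in pairs for i in p]
        assert len(pairs) == config.n_pairs
        assert len(set(flat)) == 2 * config.n_pairs
        assert len(drawn_groups) == 2 * config.n_pairs

    def test_degenerate_weights_select_only_group_one(self, scored_population):
        pop, config, _ = scored_population
        cfg = small_config(group_weights=(1.0, 0.0, 0.0, 0.0, 0.0), n_pairs=5,
                           children_per_pair=10, population_size=50)
        _, groups = rank_and_group(pop, np.random.default_rng(1), small_config())
        pairs, drawn_groups = select_pairs(groups, cfg, np.random.default_rng(5))
        assert set(drawn_groups.tolist()) == {0}

    def test_group_exhaustion_renormalizes(self, scored_population):
        pop, config, scorer = scored_population
        # tiny groups: force exhaustion of group 1
        cfg = GAConfig(population_size=20, n_pairs=2, children_per_pair=10,
                       n_groups=5, group_weights=(100.0, 1.0, 1.0, 1.0, 1.0))
        sub = Population(K=pop.K[:20], C=pop.C[:20], scorer=scorer)
        sub.score()
        _, groups = rank_and_group(sub, np.random.default_rng(1), cfg)
        # draw all 20 proposals: every pool must empty without error
        cfg2 = GAConfig(population_size=20, n_pairs=10, children_per_pair=2,
                        n_groups=5, group_weights=(100.0, 1.0, 1.0, 1.0, 1.0))
        pairs, drawn_groups = select_pairs(groups, cfg2, np.random.default_rng(5))
        assert sorted(i for p in pairs for i in p) == list(range(20))


class TestCrossover:
    def test_identical_parents_fixed_point(self, scored_population):
        pop, config, _ = scored_population
        a = (pop.K[0], pop.C[0])
        K, C = crossover(a, a, 5, np.random.default_rng(0))
        assert np.all(K == pop.K[0]) and np.all(C == pop.C[0])

    def test_explicit_mask_construction(self):
        # L=4: child takes parent A at masked loci, B elsewhere
        Ka, Ca = np.array([1, 2, 3, 4]), np.array([0, 0, 0, 0])
        Kb, Cb = np.array([5, 6, 7, 8]), np.array([1, 1, 1, 1])
        rng = np.random.default_rng(0)
        K, C = crossover((Ka, Ca), (Kb, Cb), 200, rng)
        # every child takes exactly 2 of 4 loci from parent A
        from_a = (K <= 4)
        assert (from_a.sum(axis=1) == 2).all()
        assert np.array_equal(C == 0, from_a)

    def test_mask_has_exactly_half_from_parent_a(self):
        masks = _crossover_masks(1000, 7, np.random.default_rng(1))
        assert (masks.sum(axis=1) == 3).all()  # floor(7/2)

    def test_inheritance_frequency_near_half(self):
        masks = _crossover_masks(10_000, 10, np.random.default_rng(2))
        freq = masks.mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(freq - 0.5) < 4 * se)


class TestMutation:
    def test_rate_zero_is_identity(self, scored_population):
        pop, config, scorer = scored_population
        cfg = small_config(mutation_rate=0.0)
        K, C = mutate_population(pop.K.copy(), pop.C.copy(), scorer, cfg, np.random.default_rng(0))
        assert np.array_equal(K, pop.K) and np.array_equal(C, pop.C)

    def test_rate_one_singleton_candidate_unchanged(self):
        sc = generate_scenario(ScenarioParams(n_loci=3, genes_per_locus=2, n_cell_types=3), seed=2)
        sc.bundle.loci[1].candidate_genes = sc.bundle.loci[1].candidate_genes[:1]
        cfg = small_config(mutation_rate=1.0)
        scorer = ProposalScorer(sc.bundle, cfg)
        K = np.zeros((20, 3), dtype=np.int64)
        C = np.zeros((20, 3), dtype=np.int64)
        K2, _ = mutate_population(K, C, scorer, cfg, np.random.default_rng(0))
        assert (K2[:, 1] == 0).all()  # resampled from a singleton set

    def test_event_rate_recovery(self, scored_population):
        _, _, scorer = scored_population
        cfg = small_config(mutation_rate=0.01)
        K = np.zeros((2000, scorer.n_loci), dtype=np.int64)
        C = np.zeros((2000, scorer.n_loci), dtype=np.int64)
        _, _, gene_mask, cell_mask = mutate_population(
            K, C, scorer, cfg, np.random.default_rng(0), return_events=True
        )
        n = gene_mask.size
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(gene_mask.mean() - 0.01) < 3 * se
        assert abs(cell_mask.mean() - 0.01) < 3 * se

    def test_mutated_proposals_stay_valid(self, scored_population, small_scenario):
        pop, config, scorer = scored_population
        cfg = small_config(mutation_rate=0.5)
        K, C = mutate_population(pop.K.copy(), pop.C.copy(), scorer, cfg, np.random.default_rng(1))
        mutated = Population(K=K, C=C, scorer=scorer)  # constructor validates ranges
        for i in range(0, len(mutated), 25):
            mutated.proposal(i).validate(small_scenario.bundle.loci, small_scenario.bundle.catalog)


class TestElitism:
    def test_elite_survives_and_size_conserved(self, scored_population):
        pop, config, scorer = scored_population
        ranked, _ = rank_and_group(pop, np.random.default_rng(0), config)
        elite = (ranked.K[0].copy(), ranked.C[0].copy())
        # children with strictly worse fitness: all-zero candidates
        childK = np.zeros_like(pop.K)
        childC = np.zeros_like(pop.C)
        children = Population(K=childK, C=childC, scorer=scorer)
        children.score()
        nxt = apply_elitism(children, elite, np.random.default_rng(1), config)
        assert len(nxt) == len(pop)
        assert nxt.fitness.max() >= ranked.fitness[0]

    def test_replacement_hits_lowest_group_even_if_elite_present(self, scored_population):
        pop, config, scorer = scored_population
        ranked, groups = rank_and_group(pop, np.random.default_rng(0), config)
        elite = (ranked.K[0].copy(), ranked.C[0].copy())
        children = Population(K=ranked.K.copy(), C=ranked.C.copy(), scorer=scorer)
        children.score()
        nxt = apply_elitism(children, elite, np.random.default_rng(1), config)
        # a group-5 slot now carries the elite's (duplicated) assignment
        low = groups[-1]
        matches = [
            i for i in low
            if np.array_equal(nxt.K[i], elite[0]) and np.array_equal(nxt.C[i], elite[1])
        ]
        assert matches


class TestTermination:
    config = GAConfig()

    def test_constant_trace_terminates(self):
        assert check_termination(np.ones(15), self.config)

    def test_steady_growth_does_not(self):
        m = 0.2 * 1.05 ** np.arange(30)
        assert not check_termination(m, self.config)

    def test_fires_at_expected_generation_for_flat_tail(self):
        m = np.concatenate([1.2 ** np.arange(41), np.full(40, 1.2**40)])
        g = termination_generation(m, self.config)
        assert g == 40 + self.config.smoothing_window + self.config.termination_window - 1

    def test_short_trace_is_inconclusive(self):
        assert not check_termination(np.ones(10), self.config)


class TestRun:
    def test_same_seed_identical_traces(self, small_scenario):
        cfg = small_config(n_generations=8)
        traces = []
        for _ in range(2):
            _, trace, _ = run(small_scenario.bundle, cfg, seed=123)
            traces.append(trace.to_frame())
        assert traces[0].equals(traces[1])

    def test_elite_fitness_nondecreasing_and_size_constant(self, small_scenario):
        cfg = small_config(n_generations=15)
        pop, trace, elite_history = run(small_scenario.bundle, cfg, seed=4)
        assert len(pop) == cfg.population_size
        fits = [f for _, f in elite_history]
        assert all(b >= a - 1e-12 for a, b in zip(fits, fits[1:]))
        df = trace.to_frame()
        assert (df["max_fitness"].diff().dropna() >= -1e-12).all()

    def test_population_valid_throughout(self, small_scenario):
        # Population.__post_init__ validates every generation's arrays; a run
        # completing without error certifies the invariant. Spot-check decode.
        cfg = small_config(n_generations=5)
        pop, _, _ = run(small_scenario.bundle, cfg, seed=9)
        for i in range(0, len(pop), 20):
            pop.proposal(i).validate(small_scenario.bundle.loci, small_scenario.bundle.catalog)

    def test_flat_landscape_is_stationary(self):
        # no annotation at all: every proposal scores 0, selection has no
        # gradient, and mean fitness stays exactly 0
        sc = generate_scenario(
            ScenarioParams(n_loci=5, genes_per_locus=4, n_cell_types=3,
                           signal_rate=0.0, noise_rate=0.0, lnc_fraction=0.0,
                           planted_fraction=0.0),
            seed=3,
        )
        cfg = small_config(n_generations=10)
        _, trace, _ = run(sc.bundle, cfg, seed=1)
        assert (trace.to_frame()["mean_fitness"] == 0.0).all()

    def test_finds_exhaustive_optimum_on_tiny_instance(self, tiny_scenario):
        bundle, config = tiny_scenario.bundle, tiny_scenario.config
        cfg = small_config(n_generations=30)
        scorer = ProposalScorer(bundle, cfg)
        best = _exhaustive_best_fitness(scorer)
        pop, _, _ = run(bundle, cfg, seed=0, scorer=scorer)
        assert pop.fitness.max() == pytest.approx(best)


def _exhaustive_best_fitness(scorer):
    """Enumerate every proposal of a tiny instance and return max fitness."""
    import itertools

    L = scorer.n_loci
    gene_opts = [range(int(n)) for n in scorer.n_cand]
    cell_opts = [range(scorer.n_cells)] * L
    combos = list(itertools.product(*gene_opts, *cell_opts))
    A = np.array(combos, dtype=np.int64)
    K, C = A[:, :L], A[:, L:]
    _, fitness = scorer.score_population(K, C)
    return float(fitness.max())
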