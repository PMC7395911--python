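import random
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from edsim import engine, fixtures, kpi, optimize
from edsim.optimize import (
    BaseScenario,
    Chromosome,
    GAConfig,
    GeneSpec,
    SweepSpec,
    brute_force_grid,
    default_gene_specs,
    evaluate_fitness,
    ga_run,
    sweep,
    _crossover,
    _mutate,
)
from edsim.population import ConfigError


PRIORITY = GeneSpec("priority_criteria", 0, 100, 5)


def quadratic(center):
    return lambda genes: float((genes[0] - center) ** 2)


class TestGeneSpec:
    def test_priority_grid_has_21_cells(self):
        assert len(PRIORITY.grid()) == 21

    def test_grid_membership(self):
        assert PRIORITY.contains(60)
        assert not PRIORITY.contains(57)
        assert not PRIORITY.contains(105)

    def test_default_space_is_five_dimensional(self):
        specs = default_gene_specs()
        assert [s.name for s in specs] == [
            "priority_criteria",
            "threshold_esi2",
            "threshold_esi3",
            "threshold_esi4",
            "threshold_esi5",
        ]
        bounds = {s.name: (s.lower, s.upper) for s in specs}
        assert bounds["threshold_esi2"] == (900, 3_600)
        assert bounds["threshold_esi3"] == (1_800, 5_400)
        assert bounds["threshold_esi4"] == (3_600, 9_600)
        assert bounds["threshold_esi5"] == (7_200, 14_400)

    def test_chromosome_off_grid_rejected(self):
        with pytest.raises(ConfigError):
            Chromosome((57,), (PRIORITY,))


class TestBruteForce:
    def test_quadratic_argmin(self):
        assert brute_force_grid(PRIORITY, lambda x: (x - 60) ** 2) == (60, 0.0)

    def test_constant_ties_to_smallest(self):
        assert brute_force_grid(PRIORITY, lambda x: 1.0) == (0, 1.0)

    def test_single_point_grid(self):
        assert brute_force_grid([35], lambda x: x) == (35, 35.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            brute_force_grid([], lambda x: x)


class TestGaMechanics:
    def test_zero_variation_returns_initial_point(self):
        """Point grids + no crossover/mutation: the GA cannot move."""
        specs = (GeneSpec("a", 40, 40, 5), GeneSpec("b", 1200, 1200, 60))
        cfg = GAConfig(population_size=4, crossover_rate=0.0, mutation_rate=0.0,
                       generations=5, seed=1)
        best, fit, hist = ga_run(cfg, specs, lambda g: float(sum(g)))
        assert best.genes == (40, 1200)
        assert fit == 1240.0

    def test_best_history_monotone_with_elitism(self):
        cfg = GAConfig(population_size=20, generations=25, elitism=1, seed=2)
        _, _, hist = ga_run(cfg, (PRIORITY,), quadratic(60))
        assert (hist["best"].diff().dropna() <= 0).all()

    def test_same_seed_identical_history(self):
        cfg = GAConfig(population_size=20, generations=10, seed=3)
        _, _, h1 = ga_run(cfg, (PRIORITY,), quadratic(45))
        _, _, h2 = ga_run(cfg, (PRIORITY,), quadratic(45))
        assert h1.equals(h2)

    def test_surrogate_matches_brute_force(self):
        """Paper-style validation: 1-D GA agrees with exhaustive search."""
        cfg = GAConfig(population_size=50, crossover_rate=0.7, mutation_rate=0.3,
                       generations=30, elitism=1, seed=4)
        best, fit, _ = ga_run(cfg, (PRIORITY,), quadratic(60))
        bf_x, bf_f = brute_force_grid(PRIORITY, lambda x: quadratic(60)((x,)))
        assert best.genes[0] == bf_x == 60
        assert fit == bf_f == 0.0

    def test_generations_zero_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(generations=0)

    def test_variation_operators_respect_grids(self):
        """10,000 random crossover+mutation products stay on the gene grids."""
        specs = default_gene_specs()
        rng = random.Random(5)
        parents = [tuple(s.sample(rng) for s in specs) for _ in range(200)]
        for i in range(10_000):
            a = parents[rng.randrange(len(parents))]
            b = parents[rng.randrange(len(parents))]
            c1, c2 = _crossover(a, b, rng)
            child = _mutate(c1 if i % 2 else c2, specs, 0.3, rng)
            Chromosome(child, specs)  # raises if off-grid

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        center=st.integers(min_value=0, max_value=20).map(lambda k: 5 * k),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_ga_equals_brute_force_on_random_quadratics(self, center, scale):
        f = lambda genes: scale * (genes[0] - center) ** 2
        cfg = GAConfig(population_size=50, crossover_rate=0.7, mutation_rate=0.3,
                       generations=30, elitism=1, seed=6)
        best, _, _ = ga_run(cfg, (PRIORITY,), f)
        bf_x, _ = brute_force_grid(PRIORITY, lambda x: f((x,)))
        assert best.genes[0] == bf_x == center


def tiny_base(load="light", scale=0.1, horizon=1, pc=50):
    spec = fixtures.FixtureSpec(scale=scale, load=load)
    graph = fixtures.build_fixture_graph(spec)
    arrivals, staffing, policy, sim = fixtures.build_fixture_config(spec)
    policy = replace(policy, priority_criteria=pc)
    sim = replace(sim, horizon_days=horizon, warmup_days=0)
    return BaseScenario(
        graph=graph, arrival_cfg=arrivals, staffing=staffing, policy=policy, sim_cfg=sim
    )


class TestSimulationFitness:
    def test_max_thresholds_near_empty_department_fitness_zero(self):
        base = tiny_base()
        base.arrival_cfg = replace(base.arrival_cfg, daily_mean=1.0)
        specs = default_gene_specs()
        chrom = Chromosome((50, 3_600, 5_400, 9_600, 14_400), specs)
        assert evaluate_fitness(chrom, base, replicates=3, seed=7) == 0.0

    def test_single_replicate_equals_quality_score(self):
        base = tiny_base()
        specs = default_gene_specs()
        chrom = Chromosome((50, 900, 1_800, 3_600, 7_200), specs)
        fit = evaluate_fitness(chrom, base, replicates=1, seed=8)
        policy = chrom.to_policy(base.policy)
        run_seed = optimize._replicate_seed(8, 0)
        result = engine.run(
            base.graph, base.arrival_cfg, base.staffing, policy,
            replace(base.sim_cfg, seed=run_seed),
        )
        assert fit == kpi.quality_score(result, policy.thresholds)

    def test_identical_chromosomes_identical_fitness(self):
        base = tiny_base()
        specs = default_gene_specs()
        a = Chromosome((50, 1_200, 2_400, 4_800, 9_600), specs)
        b = Chromosome((50, 1_200, 2_400, 4_800, 9_600), specs)
        assert evaluate_fitness(a, base, 2, seed=9) == evaluate_fitness(b, base, 2, seed=9)


class TestSweep:
    def test_cell_and_row_counts(self):
        base = tiny_base()
        spec = SweepSpec(
            grids=(GeneSpec("priority_criteria", 0, 100, 5),),
            base=base, replicates=2, seed=10,
        )
        table = sweep(spec)
        assert len(table) == 21 * 2
        assert table["priority_criteria"].nunique() == 21

    def test_rerun_identical(self):
        base = tiny_base()
        spec = SweepSpec(
            grids=(GeneSpec("priority_criteria", 0, 100, 50),),
            base=base, replicates=2, seed=11,
        )
        assert sweep(spec).equals(sweep(spec))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigError):
            GeneSpec("priority_criteria", 0, 100, 0)
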