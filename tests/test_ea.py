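"""Fitness arithmetic and the genetic operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ctalloc.ea import (
    Chromosome,
    EAConfig,
    PredictorSeries,
    batch_fitness,
    crossover,
    evolve,
    fitness,
    init_population,
    minmax_scale,
    mse,
    mutate,
    roulette_select,
)


def series_from(matrix) -> PredictorSeries:
    return PredictorSeries(*[np.asarray(row, dtype=float) for row in matrix])


def loop_fitness(genes, matrix, weights) -> float:
    """Independent oracle: plain-Python min-max scaling and MSE, no numpy tricks."""
    def scale(v):
        lo, hi = min(v), max(v)
        if hi == lo:
            return [0.0] * len(v)
        return [(x - lo) / (hi - lo) for x in v]

    sg = scale(list(genes))
    total = 0.0
    for w, row in zip(weights, matrix):
        sr = scale(list(row))
        total += w * sum((a - b) ** 2 for a, b in zip(sr, sg)) / len(sg)
    return total


class TestMinMaxScale:
    def test_formula(self):
        np.testing.assert_allclose(minmax_scale([2, 4, 6]), [0, 0.5, 1])

    def test_constant_series_maps_to_zeros(self):
        np.testing.assert_array_equal(minmax_scale([7, 7, 7]), [0, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_scale([])

    @given(
        v=hnp.arrays(float, st.integers(2, 30),
                     elements=st.floats(-1e6, 1e6, allow_nan=False)),
        a=st.floats(0.01, 100), b=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_positive_affine_maps(self, v, a, b):
        np.testing.assert_allclose(minmax_scale(a * v + b), minmax_scale(v), atol=1e-9)


class TestMse:
    def test_identity_is_zero(self):
        assert mse([0, 0.5, 1], [0, 0.5, 1]) == 0.0

    def test_hand_value(self):
        assert mse([0, 1], [1, 0]) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(30):
            a, b = rng.random(17), rng.random(17)
            expected = sum((x - y) ** 2 for x, y in zip(a, b)) / 17
            assert mse(a, b) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse([1, 2], [1, 2, 3])


class TestFitness:
    def test_perfect_tracking_scores_zero(self):
        genes = np.array([1, 2, 4])
        series = series_from([genes] * 5)
        assert fitness(Chromosome(genes), series, EAConfig()).total == 0.0

    def test_hand_computed_example(self):
        # four series equal the genes; population deviates; weights 0.1:
        # total = 0.1 * MSE([0,1,0.5], [0,1/3,1]) = 0.1*((2/3)^2+(1/2)^2)/3
        genes = np.array([1, 2, 4])
        series = series_from([genes, genes, genes, [100, 300, 200], genes])
        fb = fitness(Chromosome(genes), series, EAConfig())
        assert fb.total == pytest.approx(0.0231481481, abs=1e-9)
        assert fb.p_population == pytest.approx(0.2314814815, abs=1e-9)
        assert fb.p_females == 0.0

    def test_total_is_weighted_sum_of_components(self, rng):
        genes = rng.integers(0, 10, 8)
        series = series_from(rng.random((5, 8)))
        cfg = EAConfig(w_females=0.3, w_old=0.05, w_young=0.2, w_population=0.1, w_patients=0.0)
        fb = fitness(Chromosome(genes), series, cfg)
        assert fb.total == pytest.approx(float(fb.components() @ cfg.weights), rel=1e-12)

    def test_rescaling_one_series_changes_nothing(self, rng):
        genes = rng.integers(0, 10, 12)
        matrix = rng.random((5, 12))
        base = fitness(genes, series_from(matrix), EAConfig()).total
        scaled = matrix.copy()
        scaled[3] *= 1000.0
        assert fitness(genes, series_from(scaled), EAConfig()).total == pytest.approx(base, rel=1e-12)

    def test_role_permutation_symmetry_with_equal_weights(self, rng):
        genes = rng.integers(0, 10, 9)
        matrix = rng.random((5, 9))
        base = fitness(genes, series_from(matrix), EAConfig()).total
        for perm in ([1, 0, 2, 3, 4], [4, 3, 2, 1, 0]):
            assert fitness(genes, series_from(matrix[perm]), EAConfig()).total == pytest.approx(base, rel=1e-12)

    def test_length_mismatch_rejected(self):
        series = series_from(np.ones((5, 4)) * np.arange(4))
        with pytest.raises(ValueError, match="length"):
            fitness(np.array([1, 2]), series, EAConfig())

    def test_batch_matches_single(self, rng):
        matrix = rng.random((5, 10))
        series = series_from(matrix)
        cfg = EAConfig()
        pop = rng.integers(0, 15, (20, 10))
        scaled_pred = np.stack([minmax_scale(r) for r in matrix])
        _, totals = batch_fitness(pop, scaled_pred, cfg.weights)
        for row, total in zip(pop, totals):
            assert total == pytest.approx(fitness(row, series, cfg).total, rel=1e-12)


class TestInitPopulation:
    def test_shape_and_bounds(self):
        pop = init_population(EAConfig(), 130)
        assert pop.shape == (100, 130)
        assert pop.min() >= 0 and pop.max() <= 10

    def test_seeded_reproducibility(self):
        cfg = EAConfig(seed=11)
        np.testing.assert_array_equal(init_population(cfg, 20), init_population(cfg, 20))

    def test_uniform_mean(self):
        pop = init_population(EAConfig(pop_size=1000, seed=2), 100)
        # uniform on 0..10: mean 5, var 10; 3 sigma band for 1e5 draws
        sigma = np.sqrt(10.0 / pop.size)
        assert abs(pop.mean() - 5.0) < 3 * sigma


class TestRouletteSelect:
    def test_equal_fitness_is_symmetric(self, rng):
        pop = np.array([[0], [1]])
        sel = roulette_select(pop, np.array([1.0, 1.0]), EAConfig(pop_size=20_000), rng)
        assert abs((sel == 0).mean() - 0.5) < 0.02

    def test_inverse_fitness_law(self, rng):
        # f = [1, 3] -> p = (1/1)/(1/1 + 1/3) = 0.75
        pop = np.array([[0], [1]])
        sel = roulette_select(pop, np.array([1.0, 3.0]), EAConfig(pop_size=20_000), rng)
        assert abs((sel == 0).mean() - 0.75) < 0.015

    def test_zero_fitness_falls_back_to_uniform(self, rng, caplog):
        pop = np.array([[0], [1]])
        with caplog.at_level("WARNING"):
            sel = roulette_select(pop, np.array([0.0, 0.0]), EAConfig(pop_size=10_000), rng)
        assert "uniform" in caplog.text
        assert abs((sel == 0).mean() - 0.5) < 0.03


class TestCrossover:
    def test_zero_probability_is_identity(self, rng):
        pop = rng.integers(0, 10, (30, 8))
        out = crossover(pop, EAConfig(crossover_chrom_prob=0.0), rng)
        np.testing.assert_array_equal(out, pop)

    def test_forced_pair_swaps_entirely(self, rng):
        pop = np.array([[1, 2, 3], [7, 8, 9]])
        cfg = EAConfig(crossover_chrom_prob=1.0, crossover_gene_prob=1.0)
        out = crossover(pop, cfg, rng)
        np.testing.assert_array_equal(np.sort(out, axis=0), np.sort(pop, axis=0))
        assert not np.array_equal(out[0], pop[0])

    def test_per_position_multisets_conserved(self, rng):
        for _ in range(20):
            pop = rng.integers(0, 12, (25, 9))
            out = crossover(pop, EAConfig(), rng)
            np.testing.assert_array_equal(np.sort(out, axis=0), np.sort(pop, axis=0))


class TestMutate:
    def test_clamped_at_zero(self, rng):
        # gene 2 with the most negative delta (-5) clamps to 0, never -3
        pop = np.full((200, 50), 2)
        cfg = EAConfig(mutation_gene_prob=1.0)
        out = mutate(pop, cfg, rng)
        assert out.min() == 0
        assert (out <= 12).all()

    def test_zero_probability_is_identity(self, rng):
        pop = rng.integers(0, 10, (20, 20))
        out = mutate(pop, EAConfig(mutation_gene_prob=0.0), rng)
        np.testing.assert_array_equal(out, pop)

    def test_never_negative(self, rng):
        pop = rng.integers(0, 3, (100, 40))
        for _ in range(10):
            pop = mutate(pop, EAConfig(mutation_gene_prob=0.5), rng)
            assert pop.min() >= 0


class TestEvolve:
    def small_series(self, rng):
        return series_from(rng.random((5, 6)))

    def test_same_seed_same_best(self, rng):
        series = self.small_series(rng)
        cfg = EAConfig(pop_size=20, generations=50, seed=5)
        a = evolve(series, cfg)
        b = evolve(series, cfg)
        np.testing.assert_array_equal(a.best.genes, b.best.genes)
        assert a.best_fitness.total == b.best_fitness.total

    def test_history_is_monotone_non_increasing(self, rng):
        res = evolve(self.small_series(rng), EAConfig(pop_size=20, generations=80, seed=3))
        assert np.all(np.diff(res.history) <= 0)
        assert len(res.history) == 80

    def test_improves_on_initial_population(self, rng):
        series = self.small_series(rng)
        res = evolve(series, EAConfig(pop_size=30, generations=120, seed=2))
        assert res.best_fitness.total <= res.history[0]

    def test_requires_two_units(self, units130):
        with pytest.raises(ValueError, match="2 units"):
            evolve(units130.iloc[:1], EAConfig(generations=2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="pop_size"):
            EAConfig(pop_size=1)
        with pytest.raises(ValueError, match="mutation_low"):
            EAConfig(mutation_low=3, mutation_high=1)


class TestFitnessLoopOracle:
    def test_random_instances_match_independent_recomputation(self, rng):
        cfg = EAConfig()
        for _ in range(25):
            g = rng.integers(1, 12)
            genes = rng.integers(0, 20, g)
            matrix = rng.random((5, g)) * rng.uniform(1, 100)
            got = fitness(genes, series_from(matrix), cfg).total
            want = loop_fitness(genes, matrix, cfg.weights)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
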