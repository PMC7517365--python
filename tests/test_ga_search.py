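import numpy as np
import pytest

from mkmd import (
    DissimilarityStack,
    GAConfig,
    Genome,
    PrototypeMask,
    build_stacks,
    evaluate_f1,
    evaluate_f2,
    evolve,
)
from mkmd.ga_search import (
    mutate,
    project_simplex,
    random_genome,
    roulette_select,
    scattered_crossover,
)
from tests.conftest import random_representation_sets


@pytest.fixture(scope="module")
def tiny_problem():
    """Well-separated two-view problem: 16 train / 8 val patterns."""
    rng = np.random.default_rng(0)

    def make(n):
        sets, labels = [], []
        for i in range(n):
            cls = i % 2
            vec = rng.normal(cls * 6.0, 0.5, 3)
            sets.append(
                random_representation_sets(1, seed=rng.integers(1e6))[0].__class__(
                    {1: vec, 2: rng.normal(0, 1, 3)}
                )
            )
            labels.append(1 if cls else -1)
        return sets, np.array(labels)

    train, y_tr = make(16)
    val, y_va = make(8)
    ts, vs, _ = build_stacks(train, val, val)
    return ts, vs, y_tr, y_va


def _genome(n_train, beta=(0.5, 0.5), gamma=(1.0, 1.0), nu=0.5, bits=None):
    mask = PrototypeMask.all_ones(n_train) if bits is None else PrototypeMask(bits=bits)
    return Genome(nu=nu, beta=beta, gamma=gamma, mask=mask)


class TestFitnessFunctions:
    def test_separable_problem_reaches_perfect_f1(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        f = evaluate_f1(_genome(16, beta=(1.0, 0.0), gamma=(0.05, 1.0)), ts, vs, y_tr, y_va)
        assert f == pytest.approx(1.0)

    def test_f1_deterministic_across_calls(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        g = _genome(16, gamma=(0.1, 0.1))
        assert evaluate_f1(g, ts, vs, y_tr, y_va) == evaluate_f1(g, ts, vs, y_tr, y_va)

    def test_f2_omega_one_is_one_minus_jbar(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        g = _genome(16, beta=(1.0, 0.0), gamma=(0.05, 1.0))
        j_bar = evaluate_f1(g, ts, vs, y_tr, y_va)
        assert evaluate_f2(g, ts, vs, y_tr, y_va, omega=1.0) == pytest.approx(1 - j_bar)

    def test_f2_omega_zero_is_mask_density(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        bits = (1, 1, 1, 1) + (0,) * 12  # 4 of 16
        g = _genome(16, bits=bits)
        assert evaluate_f2(g, ts, vs, y_tr, y_va, omega=0.0) == pytest.approx(0.25)

    def test_f2_arithmetic(self):
        # omega=0.5, J_bar=0.8, density 0.3 -> 0.5*0.2 + 0.5*0.3 = 0.25
        assert 0.5 * (1 - 0.8) + 0.5 * 0.3 == pytest.approx(0.25)

    def test_orientation_pairing(self, tiny_problem):
        # on identical predictions, higher f1 must mean lower f2 (omega=1)
        ts, vs, y_tr, y_va = tiny_problem
        good = _genome(16, beta=(1.0, 0.0), gamma=(0.05, 1.0))
        bad = _genome(16, beta=(0.0, 1.0), gamma=(50.0, 50.0))
        f1_good = evaluate_f1(good, ts, vs, y_tr, y_va)
        f1_bad = evaluate_f1(bad, ts, vs, y_tr, y_va)
        f2_good = evaluate_f2(good, ts, vs, y_tr, y_va, omega=1.0)
        f2_bad = evaluate_f2(bad, ts, vs, y_tr, y_va, omega=1.0)
        assert f1_good > f1_bad
        assert f2_good < f2_bad


class TestOperators:
    def test_roulette_degenerate_certainty(self):
        rng = np.random.default_rng(0)
        pop = ["a", "b", "c"]
        parents = roulette_select(pop, [1.0, 0.0, 0.0], rng, 20)
        assert set(parents) == {"a"}

    def test_roulette_uniform_within_3_sigma(self):
        rng = np.random.default_rng(1)
        pop = list(range(4))
        draws = 10_000
        parents = roulette_select(pop, [2.0, 2.0, 2.0, 2.0], rng, draws)
        counts = np.bincount(parents, minlength=4)
        expected = draws / 4
        sigma = np.sqrt(draws * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_roulette_scale_invariance(self):
        pop = list(range(3))
        a = roulette_select(pop, [1.0, 2.0, 3.0], np.random.default_rng(7), 5000)
        b = roulette_select(pop, [2.0, 4.0, 6.0], np.random.default_rng(7), 5000)
        assert a == b

    def test_crossover_identical_parents(self):
        rng = np.random.default_rng(2)
        g = random_genome(3, 8, rng)
        child = scattered_crossover(g, g, np.random.default_rng(3))
        assert child == g

    def test_crossover_genes_from_parents(self):
        rng = np.random.default_rng(4)
        a, b = random_genome(3, 10, rng), random_genome(3, 10, rng)
        child = scattered_crossover(a, b, rng)
        for bit, ba, bb in zip(child.mask.bits, a.mask.bits, b.mask.bits):
            assert bit in (ba, bb)
        assert np.asarray(child.beta).sum() == pytest.approx(1.0)

    def test_mutation_respects_bounds(self):
        rng = np.random.default_rng(5)
        config = GAConfig(population=10, generations=10, mutation_sigma0=0.5)
        g = random_genome(4, 12, rng)
        for gen in range(10):
            g = mutate(g, gen, config, rng)
            assert 1e-3 <= g.nu <= 1.0
            assert np.asarray(g.beta).sum() == pytest.approx(1.0)
            assert np.all(np.asarray(g.gamma) > 0) and np.all(np.asarray(g.gamma) <= 100)
            assert g.mask.n_selected >= 1

    def test_zero_mutation_is_identity(self):
        rng = np.random.default_rng(6)
        g = random_genome(2, 6, rng)
        config = GAConfig(
            population=10, generations=10, mutation_sigma0=0.0, sigma_floor=0.0,
            mask_flip_prob=0.0,
        )
        assert mutate(g, 0, config, rng) == g

    def test_simplex_projection(self):
        np.testing.assert_allclose(project_simplex(np.array([2.0, 2.0])), [0.5, 0.5])
        np.testing.assert_allclose(project_simplex(np.array([0.0, 0.0, 0.0])), 1 / 3)
        assert project_simplex(np.array([-1.0, 0.5])).sum() == pytest.approx(1.0)


class TestEvolve:
    def test_elitism_monotone_best_fitness(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        config = GAConfig(population=8, generations=6, seed=0)
        _, trace = evolve(ts, vs, y_tr, y_va, config, fitness="f1")
        assert np.all(np.diff(trace.best_fitness) >= 0)

    def test_same_seed_identical_trace(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        config = GAConfig(population=8, generations=4, seed=11)
        g1, t1 = evolve(ts, vs, y_tr, y_va, config, fitness="f1")
        g2, t2 = evolve(ts, vs, y_tr, y_va, config, fitness="f1")
        assert g1 == g2 and t1.best_fitness == t2.best_fitness

    def test_selection_disabled_keeps_all_ones_mask(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        config = GAConfig(population=8, generations=4, seed=2)
        genome, _ = evolve(ts, vs, y_tr, y_va, config, fitness="f1", selection_enabled=False)
        assert genome.mask.n_selected == len(genome.mask) == ts.shape[1]

    def test_f2_best_fitness_non_increasing(self, tiny_problem):
        ts, vs, y_tr, y_va = tiny_problem
        config = GAConfig(population=8, generations=5, seed=3)
        _, trace = evolve(ts, vs, y_tr, y_va, config, fitness="f2")
        assert np.all(np.diff(trace.best_fitness) <= 0)
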