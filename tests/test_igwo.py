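"""Gray wolf optimizer: encoding, moves, archive, termination contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melanopt import igwo


class TestGenomeEncoding:
    @pytest.mark.parametrize(
        "h, x, c, expected",
        [(12, 100, 2, 12 * 101 + 2 * 13), (5, 1, 1, 5 * 2 + 1 * 6)],
    )
    def test_active_gene_count(self, h, x, c, expected):
        g = np.zeros(igwo.genome_length(x, c))
        g[0] = h
        g[1:] = np.arange(1, g.size) * 1e-4
        spec = igwo.decode_genome(g, x, c)
        used = (spec.hidden_weights.size + spec.hidden_biases.size
                + spec.output_weights.size + spec.output_biases.size)
        assert used == expected
        assert spec.n_hidden == h
        # genes are consumed in order: last active gene is expected-th
        assert spec.output_biases[-1] == pytest.approx(expected * 1e-4)

    def test_hidden_size_rounding(self):
        g = np.zeros(igwo.genome_length(3, 2))
        g[0] = 12.4
        assert igwo.decode_genome(g, 3, 2).n_hidden == 12
        g[0] = 12.6
        assert igwo.decode_genome(g, 3, 2).n_hidden == 13

    @settings(derandomize=True, max_examples=100)
    @given(h=st.floats(5.0, 30.0), x=st.integers(1, 200), c=st.integers(1, 4))
    def test_decoded_weight_count_matches_formula(self, h, x, c):
        g = np.zeros(igwo.genome_length(x, c))
        g[0] = h
        spec = igwo.decode_genome(g, x, c)
        hh = spec.n_hidden
        assert 5 <= hh <= 30
        used = (spec.hidden_weights.size + spec.hidden_biases.size
                + spec.output_weights.size + spec.output_biases.size)
        assert used == hh * (x + 1) + c * (hh + 1)

    def test_bounds_arrays(self):
        lower, upper = igwo.genome_bounds(10, 2)
        assert lower[0] == 5 and upper[0] == 30
        assert np.all(lower[1:] == -2) and np.all(upper[1:] == 2)


class TestLeaderMove:
    def test_a_zero_collapses_to_leader_mean(self, rng):
        dim = 6
        leaders = [rng.random(dim) for _ in range(3)]
        pos = rng.random(dim)
        out = igwo.leader_move(pos, leaders, 0.0, rng,
                               np.full(dim, -10.0), np.full(dim, 10.0))
        assert np.allclose(out, np.mean(leaders, axis=0))

    def test_fixed_point_when_leaders_equal_position(self, rng):
        pos = rng.random(4)
        out = igwo.leader_move(pos, [pos, pos, pos], 0.0, rng,
                               np.full(4, -10.0), np.full(4, 10.0))
        assert np.allclose(out, pos)

    def test_bounds_respected_over_many_draws(self, rng):
        lower, upper = np.full(5, -2.0), np.full(5, 2.0)
        for _ in range(10_000 // 10):
            leaders = [rng.uniform(-2, 2, 5) for _ in range(3)]
            pos = rng.uniform(-2, 2, 5)
            a = rng.uniform(0, 2)
            out = igwo.leader_move(pos, leaders, a, rng, lower, upper)
            assert np.all(out >= lower) and np.all(out <= upper)


class TestArchive:
    def test_first_member_gets_unit_probability(self):
        archive = igwo.Archive(capacity=10)
        igwo.update_archive(archive, [(np.array([0.1, 0.2]), 0.3)])
        assert len(archive) == 1
        assert np.allclose(archive.probabilities, [1.0])

    def test_probability_formula(self):
        archive = igwo.Archive(capacity=10)
        igwo.update_archive(archive, [(np.array([1.0]), 0.6)])
        igwo.update_archive(archive, [(np.array([0.0]), 0.2)])
        # z_i = (1 - fit_i) / sum(1 - fit_j) = (0.4, 0.8) / 1.2
        assert np.allclose(archive.probabilities, [0.4 / 1.2, 0.8 / 1.2])
        assert archive.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_not_inserted(self):
        archive = igwo.Archive(capacity=10)
        g = np.array([0.5, 0.5])
        igwo.update_archive(archive, [(g, 0.3)])
        igwo.update_archive(archive, [(g.copy(), 0.1)])
        assert len(archive) == 1

    def test_mean_fitness_gate(self):
        archive = igwo.Archive(capacity=10)
        igwo.update_archive(archive, [(np.array([0.0]), 0.4)])
        igwo.update_archive(archive, [(np.array([1.0]), 0.2)])
        # mean fit = 0.3: a 0.35 candidate is rejected, a 0.25 accepted
        igwo.update_archive(archive, [(np.array([2.0]), 0.35)])
        assert len(archive) == 2
        igwo.update_archive(archive, [(np.array([3.0]), 0.25)])
        assert len(archive) == 3

    def test_capacity_evicts_worst(self):
        archive = igwo.Archive(capacity=2)
        igwo.update_archive(archive, [(np.array([0.0]), 0.5)])
        igwo.update_archive(archive, [(np.array([1.0]), 0.3)])
        igwo.update_archive(archive, [(np.array([2.0]), 0.1)])
        assert len(archive) == 2
        assert archive.fitnesses.max() == pytest.approx(0.3)


class TestRouletteSelect:
    def test_single_member_always_chosen(self, rng):
        archive = igwo.Archive(capacity=5)
        igwo.update_archive(archive, [(np.array([0.0]), 0.4)])
        assert np.all(igwo.roulette_select(archive, 10, rng) == 0)

    def test_returns_k_indices(self, rng):
        archive = igwo.Archive(capacity=5)
        igwo.update_archive(archive, [(np.array([0.0]), 0.2),
                                      (np.array([1.0]), 0.2)])
        assert igwo.roulette_select(archive, 3, rng).shape == (3,)

    def test_empirical_frequencies_match_probabilities(self, rng):
        # two members at equal fitness -> Z = (0.5, 0.5)
        archive = igwo.Archive(capacity=5,
                               members=[(np.array([0.0]), 0.5),
                                        (np.array([1.0]), 0.5)])
        draws = igwo.roulette_select(archive, 100_000, rng)
        freq = np.mean(draws == 0)
        assert abs(freq - 0.5) < 0.01

    def test_empty_archive_rejected(self, rng):
        with pytest.raises(ValueError):
            igwo.roulette_select(igwo.Archive(), 3, rng)


def _sphere(g):
    return min(1.0, float(np.mean(np.asarray(g) ** 2)))


BOUNDS5 = (np.full(5, -2.0), np.full(5, 2.0))


class TestOptimize:
    def test_a_schedule_linear_two_to_zero(self):
        assert igwo.a_schedule(0, 300) == 2.0
        assert igwo.a_schedule(300, 300) == 0.0
        assert igwo.a_schedule(75, 300) == pytest.approx(1.5)

    def test_zero_fitness_terminates_first_iteration(self):
        cfg = igwo.IGWOConfig(population_size=6, max_iterations=50,
                              stagnation_limit=10, seed=0)
        res = igwo.optimize(lambda g: 0.0, cfg, BOUNDS5)
        assert res.termination == "zero_fitness"
        assert res.n_iterations == 1
        assert res.best_fitness == 0.0

    def test_constant_fitness_stagnates_after_m(self):
        m = 7
        cfg = igwo.IGWOConfig(population_size=6, max_iterations=50,
                              stagnation_limit=m, seed=0)
        res = igwo.optimize(lambda g: 0.5, cfg, BOUNDS5)
        assert res.termination == "stagnation"
        # first iteration establishes the best, then m stagnant iterations
        assert res.n_iterations == m + 1

    def test_iteration_budget_respected(self):
        cfg = igwo.IGWOConfig(population_size=6, max_iterations=5,
                              stagnation_limit=50, seed=0)
        res = igwo.optimize(_sphere, cfg, BOUNDS5)
        assert res.termination == "max_iterations"
        assert res.n_iterations == 5

    def test_best_so_far_history_non_increasing(self):
        cfg = igwo.IGWOConfig(population_size=10, max_iterations=30,
                              stagnation_limit=30, seed=2)
        res = igwo.optimize(_sphere, cfg, BOUNDS5)
        assert np.all(np.diff(res.history) <= 0)

    def test_improves_over_initial_population(self):
        bounds = (np.full(10, -2.0), np.full(10, 2.0))
        wins = 0
        for s in range(10):
            cfg = igwo.IGWOConfig(population_size=20, max_iterations=50,
                                  stagnation_limit=50, seed=s)
            res = igwo.optimize(_sphere, cfg, bounds)
            wins += res.history[-1] < res.history[0]
        assert wins >= 9

    def test_out_of_range_fitness_rejected(self):
        cfg = igwo.IGWOConfig(population_size=6, max_iterations=5,
                              stagnation_limit=5, seed=0)
        with pytest.raises(ValueError):
            igwo.optimize(lambda g: 1.5, cfg, BOUNDS5)


def textbook_gwo(fitness_fn, n, T, m, seed, lower, upper):
    """Independently coded canonical GWO sharing the documented RNG contract
    (uniform init; per wolf, per leader: r1 then r2 as dim-vectors)."""
    rng = np.random.default_rng(seed)
    dim = lower.size
    wolves = rng.uniform(lower, upper, size=(n, dim))
    best_val = np.inf
    best_pos = None
    stagn = 0
    history = []
    for t in range(1, T + 1):
        values = np.array([fitness_fn(w) for w in wolves])
        ranks = np.argsort(values, kind="stable")
        alpha, beta, delta = (wolves[ranks[0]].copy(), wolves[ranks[1]].copy(),
                              wolves[ranks[2]].copy())
        if values[ranks[0]] < best_val:
            best_val = float(values[ranks[0]])
            best_pos = alpha.copy()
            stagn = 0
        else:
            stagn += 1
        history.append(best_val)
        if best_val == 0.0 or stagn >= m or t == T:
            break
        a = 2.0 - 2.0 * t / T
        for i in range(n):
            new = np.zeros(dim)
            for lead in (alpha, beta, delta):
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                big_a = 2 * a * r1 - a
                c = 2 * r2
                d = np.abs(c * lead - wolves[i])
                new += lead - big_a * d
            wolves[i] = np.minimum(np.maximum(new / 3.0, lower), upper)
    return best_pos, best_val, np.array(history)


class TestEquivalences:
    def test_gwo_mode_matches_textbook_oracle(self):
        lower, upper = np.full(6, -2.0), np.full(6, 2.0)
        cfg = igwo.IGWOConfig(population_size=8, max_iterations=25,
                              stagnation_limit=25, seed=5, mode="gwo")
        res = igwo.optimize(_sphere, cfg, (lower, upper))
        pos, val, hist = textbook_gwo(_sphere, 8, 25, 25, 5, lower, upper)
        assert np.array_equal(res.history, hist)
        assert res.best_fitness == val
        assert np.array_equal(res.best_genome, pos)

    def test_empty_archive_makes_igwo_identical_to_gwo(self):
        lower, upper = np.full(6, -2.0), np.full(6, 2.0)
        base = dict(population_size=8, max_iterations=20, stagnation_limit=20,
                    seed=3)
        r_igwo = igwo.optimize(_sphere, igwo.IGWOConfig(
            mode="igwo", archive_capacity=0, **base), (lower, upper))
        r_gwo = igwo.optimize(_sphere, igwo.IGWOConfig(
            mode="gwo", **base), (lower, upper))
        assert np.array_equal(r_igwo.best_genome, r_gwo.best_genome)
        assert np.array_equal(r_igwo.history, r_gwo.history)
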