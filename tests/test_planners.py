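import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rosepath.planners import (
    ACOConfig,
    GAConfig,
    PermutationError,
    PlannerError,
    aco_tour,
    brute_force_optimal,
    dynamic_ga_params,
    ga_tour,
    make_tour,
    mutation_rate,
    nearest_neighbor_tour,
    plain_ga_config,
    reciprocating_tour,
    tour_length,
    two_opt,
)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


class TestTourLength:
    def test_triangle_perimeter(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        assert tour_length([0, 1, 2], pts, closed=True) == pytest.approx(12.0)
        assert tour_length([0, 1, 2], pts, closed=False) == pytest.approx(8.0)

    def test_single_point_zero(self):
        assert tour_length([0], np.array([[2.0, 3.0]]), closed=True) == 0.0

    def test_zero_points_rejected(self):
        with pytest.raises(PlannerError):
            tour_length([], np.empty((0, 2)))

    @pytest.mark.parametrize("bad", [[0, 0, 1], [0, 1], [0, 1, 4]])
    def test_non_permutation_rejected(self, bad):
        pts = np.zeros((3, 2))
        with pytest.raises(PermutationError):
            tour_length(bad, pts)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 10), shift=st.integers(1, 9))
    def test_closed_length_invariant_under_rotation_and_reversal(self, seed, n, shift):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(n, 2))
        order = rng.permutation(n)
        base = tour_length(order, pts, closed=True)
        rotated = np.roll(order, shift % n)
        assert tour_length(rotated, pts) == pytest.approx(base)
        assert tour_length(order[::-1], pts) == pytest.approx(base)


class TestReciprocating:
    def test_serpentine_on_unit_square(self):
        tour = reciprocating_tour(SQUARE, band_height=0.5)
        path = [tuple(SQUARE[i]) for i in tour.order]
        assert path == [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
        assert tour.length == pytest.approx(4.0)

    def test_collinear_row_is_x_sort(self, rng):
        xs = rng.uniform(0, 100, size=12)
        pts = np.column_stack([xs, np.full(12, 5.0)])
        tour = reciprocating_tour(pts, band_height=10.0)
        assert tour.open_length == pytest.approx(xs.max() - xs.min())

    def test_single_point(self):
        tour = reciprocating_tour(np.array([[3.0, 7.0]]))
        assert tour.order == (0,) and tour.length == 0.0

    def test_bad_band_height(self):
        with pytest.raises(PlannerError):
            reciprocating_tour(SQUARE, band_height=-1.0)

    def test_visits_every_point_once(self, rng):
        pts = rng.uniform(0, 500, size=(40, 2))
        tour = reciprocating_tour(pts)
        assert sorted(tour.order) == list(range(40))


class TestNearestNeighbor:
    def test_monotone_chain(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert nearest_neighbor_tour(pts, 0).order == (0, 1, 2)

    def test_tie_broken_toward_lower_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        assert nearest_neighbor_tour(pts, 0).order == (0, 1, 2)

    def test_invalid_start(self):
        with pytest.raises(PlannerError):
            nearest_neighbor_tour(SQUARE, start_index=9)

    def test_optimal_for_three_points(self, rng):
        pts = rng.uniform(0, 10, size=(3, 2))
        nn = nearest_neighbor_tour(pts, 0)
        assert nn.length == pytest.approx(brute_force_optimal(pts).length)


class TestTwoOpt:
    def test_uncrosses_square(self):
        crossing = make_tour([0, 3, 1, 2], SQUARE)  # the bow-tie order
        assert crossing.length == pytest.approx(2 + 2 * np.sqrt(2))
        fixed = two_opt(crossing, SQUARE)
        assert fixed.length == pytest.approx(4.0)

    def test_optimal_triangle_unchanged(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        tour = make_tour([0, 1, 2], pts)
        assert two_opt(tour, pts).length == pytest.approx(tour.length)

    def test_two_points_noop(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert two_opt(make_tour([0, 1], pts), pts).order == (0, 1)

    def test_never_lengthens_and_reaches_local_optimum(self, rng):
        from conftest import proper_crossing_count

        pts = rng.uniform(0, 100, size=(15, 2))
        start = make_tour(rng.permutation(15), pts)
        out = two_opt(start, pts)
        assert out.length <= start.length + 1e-9
        assert proper_crossing_count(out.order, pts) == 0


class TestSchedules:
    def test_mutation_rate_endpoints(self):
        cfg = GAConfig(max_generations=101, mutation_start=0.20, mutation_end=0.02)
        assert mutation_rate(0, cfg) == pytest.approx(0.20)
        assert mutation_rate(100, cfg) == pytest.approx(0.02)
        assert mutation_rate(50, cfg) == pytest.approx(0.11)

    def test_mutation_rate_range_check(self):
        cfg = GAConfig(max_generations=50)
        with pytest.raises(PlannerError):
            mutation_rate(50, cfg)
        with pytest.raises(PlannerError):
            mutation_rate(-1, cfg)

    def test_single_generation_schedule(self):
        cfg = GAConfig(max_generations=1)
        assert mutation_rate(0, cfg) == cfg.mutation_start

    @pytest.mark.parametrize(
        "n,expected",
        [(3, (20, 50)), (25, (100, 250)), (100, (120, 400)), (1, (20, 50))],
    )
    def test_dynamic_params_clamped_schedule(self, n, expected):
        assert dynamic_ga_params(n) == expected


class TestGeneticAlgorithm:
    def test_never_worse_than_seed_orders(self, rng):
        pts = rng.uniform(0, 300, size=(25, 2))
        recip = reciprocating_tour(pts)
        nn = nearest_neighbor_tour(pts, 0)
        got = ga_tour(
            pts,
            GAConfig(population_size=40, max_generations=60, rng_seed=3),
            seed_orders=[recip.order, nn.order],
        )
        assert got.length <= min(recip.length, nn.length) + 1e-9

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.uniform(0, 300, size=(18, 2))
        cfg = GAConfig(population_size=40, max_generations=80, rng_seed=11)
        a, b = ga_tour(pts, cfg), ga_tour(pts, cfg)
        assert a.order == b.order and a.length == b.length

    def test_matches_oracle_on_small_instances(self):
        for k in range(10):
            rng = np.random.default_rng(500 + k)
            pts = rng.uniform(0, 100, size=(7, 2))
            opt = brute_force_optimal(pts).length
            pop, gens = dynamic_ga_params(7)
            got = ga_tour(
                pts, GAConfig(population_size=pop, max_generations=gens, rng_seed=k)
            ).length
            assert got >= opt - 1e-9
            assert got == pytest.approx(opt)

    def test_plain_ablation_strips_hybrid_features(self):
        cfg = plain_ga_config(GAConfig(population_size=30, max_generations=40))
        assert cfg.greedy_seed_fraction == 0.0
        assert cfg.two_opt_every == 0
        assert cfg.mutation_start == cfg.mutation_end  # constant rate

    def test_degenerate_scene_rejected(self):
        with pytest.raises(PlannerError):
            ga_tour(np.array([[0.0, 0.0]]))

    def test_tolerates_coincident_points(self):
        pts = np.array([[5.0, 5.0]] * 4 + [[9.0, 9.0]])
        tour = ga_tour(pts, GAConfig(population_size=20, max_generations=50))
        assert sorted(tour.order) == list(range(5))
        assert tour.length == pytest.approx(2 * np.hypot(4, 4))


class TestAntColony:
    def test_matches_oracle_on_square_plus_center(self):
        pts = np.vstack([SQUARE * 10, [[5.0, 5.0]]])
        opt = brute_force_optimal(pts).length
        hits = sum(
            aco_tour(pts, ACOConfig(rng_seed=s)).length == pytest.approx(opt)
            for s in range(30)
        )
        assert hits >= 27  # >= 90% of seeds find the optimum

    def test_greedy_limit_reproduces_nearest_neighbor(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        cfg = ACOConfig(ant_count=1, iterations=1, alpha=0.0, beta=50.0, rng_seed=0)
        got = aco_tour(pts, cfg)
        start = got.order[0]
        assert got.order == nearest_neighbor_tour(pts, start).order

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.uniform(0, 100, size=(12, 2))
        a = aco_tour(pts, ACOConfig(rng_seed=5))
        b = aco_tour(pts, ACOConfig(rng_seed=5))
        assert a.order == b.order

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ACOConfig(evaporation=1.5)


class TestBruteForce:
    def test_square_perimeter(self):
        assert brute_force_optimal(SQUARE).length == pytest.approx(4.0)

    def test_two_points_out_and_back(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert brute_force_optimal(pts).length == pytest.approx(10.0)

    def test_triangle_is_order_independent(self, rng):
        pts = rng.uniform(0, 10, size=(3, 2))
        perim = tour_length([0, 1, 2], pts)
        assert brute_force_optimal(pts).length == pytest.approx(perim)

    def test_size_guard(self):
        with pytest.raises(PlannerError):
            brute_force_optimal(np.zeros((10, 2)))

    def test_removing_a_point_never_increases_optimum(self, rng):
        pts = rng.uniform(0, 100, size=(7, 2))
        full = brute_force_optimal(pts).length
        reduced = brute_force_optimal(pts[:-1]).length
        assert reduced <= full + 1e-9
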