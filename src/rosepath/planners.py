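"""Tour objective and route constructors.

The objective is the closed Euclidean tour length

    F(p) = sum_{i=1}^{n-1} d(p_i, p_{i+1}) + d(p_n, p_1),

the return edge closing the harvesting loop. Planners provided:

- :func:`reciprocating_tour` — boustrophedon band sweep (sorting-based,
  O(n log n), millisecond-scale);
- :func:`nearest_neighbor_tour` — greedy construction;
- :func:`two_opt` — first-improvement segment-reversal local search;
- :func:`ga_tour` — hybrid genetic algorithm: greedy + random
  initialization, elitism + tournament selection, order crossover,
  linearly decaying inversion mutation, periodic 2-opt polish, and
  early stopping after a patience of stagnant generations;
- :func:`aco_tour` — standard ant-system baseline;
- :func:`brute_force_optimal` — exact enumeration oracle for tiny n.

All randomized planners draw from a single seeded generator per call
and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

_STAGNATION_TOL = 1e-9  # absolute length tolerance for "no improvement"


class PlannerError(ValueError):
    pass


class PermutationError(PlannerError):
    """A tour order is not a permutation of the waypoint indices."""


@dataclass(frozen=True)
class Tour:
    """An ordering of waypoint indices with its Euclidean length.

    ``length`` is the closed-loop length when ``closed`` is true. The
    open (no return edge) length is always carried alongside for
    reporting.
    """

    order: tuple[int, ...]
    closed: bool
    length: float
    open_length: float

    @property
    def n(self) -> int:
        return len(self.order)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise PlannerError(f"points must be (n, 2), got shape {pts.shape}")
    return pts


def _check_permutation(order, n: int) -> np.ndarray:
    idx = np.asarray(order, dtype=int)
    if idx.size != n or not np.array_equal(np.sort(idx), np.arange(n)):
        raise PermutationError(
            f"order must be a permutation of 0..{n - 1}, got {list(order)!r}"
        )
    return idx


def tour_length(order, points, closed: bool = True) -> float:
    """Euclidean length of a tour; the closing edge is added iff ``closed``."""
    pts = _as_points(points)
    if len(pts) == 0:
        raise PlannerError("cannot evaluate a tour over zero points")
    idx = _check_permutation(order, len(pts))
    if len(idx) == 1:
        return 0.0
    p = pts[idx]
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
    if closed:
        seg += float(np.linalg.norm(p[-1] - p[0]))
    return float(seg)


def make_tour(order, points, closed: bool = True) -> Tour:
    """Bundle an order into a :class:`Tour` with both lengths computed."""
    pts = _as_points(points)
    idx = _check_permutation(order, len(pts))
    open_len = tour_length(idx, pts, closed=False)
    closed_len = tour_length(idx, pts, closed=True)
    return Tour(
        order=tuple(int(i) for i in idx),
        closed=closed,
        length=closed_len if closed else open_len,
        open_length=open_len,
    )


# ---------------------------------------------------------------------------
# deterministic constructors
# ---------------------------------------------------------------------------

def reciprocating_tour(points, band_height: float | None = None) -> Tour:
    """Serpentine (boustrophedon) traversal: horizontal bands, alternating
    sweep direction.

    Points are bucketed into bands of ``band_height`` pixels by y; bands
    are visited top to bottom and sorted by x, the direction alternating
    between successive non-empty bands. Reduces planning to sorting.

    When ``band_height`` is omitted it defaults to the point-set y-span
    divided by ceil(sqrt(n)), giving roughly square bands.
    """
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        raise PlannerError("reciprocating_tour requires at least one point")
    if n == 1:
        return make_tour([0], pts)
    y = pts[:, 1]
    y_min, y_span = float(y.min()), float(y.max() - y.min())
    if band_height is None:
        band_height = max(y_span / math.ceil(math.sqrt(n)), 1e-9)
    if band_height <= 0:
        raise PlannerError("band_height must be positive")
    bands = np.floor((y - y_min) / band_height).astype(int)
    order: list[int] = []
    sweep_left_to_right = True
    for b in np.unique(bands):  # unique() is sorted: top-to-bottom
        members = np.flatnonzero(bands == b)
        within = members[np.argsort(pts[members, 0], kind="stable")]
        if not sweep_left_to_right:
            within = within[::-1]
        order.extend(int(i) for i in within)
        sweep_left_to_right = not sweep_left_to_right
    return make_tour(order, pts)


def nearest_neighbor_tour(points, start_index: int = 0) -> Tour:
    """Greedy construction: hop to the closest unvisited point.

    Distance ties are broken toward the lowest index, making the
    construction deterministic.
    """
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        raise PlannerError("nearest_neighbor_tour requires at least one point")
    if not 0 <= start_index < n:
        raise PlannerError(f"start_index {start_index} out of range for n={n}")
    visited = np.zeros(n, dtype=bool)
    order = [start_index]
    visited[start_index] = True
    current = start_index
    for _ in range(n - 1):
        d = np.linalg.norm(pts - pts[current], axis=1)
        d[visited] = np.inf
        current = int(np.argmin(d))  # argmin takes the lowest index on ties
        order.append(current)
        visited[current] = True
    return make_tour(order, pts)


# ---------------------------------------------------------------------------
# 2-opt local search
# ---------------------------------------------------------------------------

def _two_opt_order(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """First-improvement 2-opt sweeps on a closed tour until locally optimal."""
    order = order.copy()
    n = len(order)
    if n < 4:
        return order
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            a, b = order[i], order[(i + 1) % n]
            # candidate second edges (c, d) for j in i+2 .. n-1 (skip adjacent)
            j_hi = n if i > 0 else n - 1  # j = n-1 with i = 0 shares node 0
            js = np.arange(i + 2, j_hi)
            if js.size == 0:
                continue
            c = order[js]
            d = order[(js + 1) % n]
            gain = dist[a, b] + dist[c, d] - dist[a, c] - dist[b, d]
            k = np.flatnonzero(gain > _STAGNATION_TOL)
            if k.size:
                j = int(js[k[0]])  # first improving move in scan order
                order[i + 1 : j + 1] = order[i + 1 : j + 1][::-1]
                improved = True
    return order


def two_opt(tour: Tour | Sequence[int], points, dist: np.ndarray | None = None) -> Tour:
    """Refine a tour with first-improvement 2-opt segment reversals.

    Terminates at a 2-opt local optimum of the closed tour, which on
    Euclidean instances contains no properly crossing edge pair. The
    output length never exceeds the input length.
    """
    pts = _as_points(points)
    order = np.asarray(tour.order if isinstance(tour, Tour) else tour, dtype=int)
    _check_permutation(order, len(pts))
    if dist is None:
        dist = squareform(pdist(pts)) if len(pts) > 1 else np.zeros((1, 1))
    return make_tour(_two_opt_order(order, dist), pts)


# ---------------------------------------------------------------------------
# hybrid genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Hybrid-GA hyperparameters.

    ``population_size`` (N) and ``max_generations`` (G) are clamped to
    small constants by :func:`dynamic_ga_params` so total work stays
    O(G * N * n); the defaults here are the schedule's lower clamps.
    ``mutation_start``/``mutation_end`` define the linear decay of the
    inversion-mutation probability over generations; evolution stops
    early after ``stagnation_patience`` generations without improvement
    of the best length.
    """

    population_size: int = 20
    max_generations: int = 50
    elite_count: int = 2
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_start: float = 0.20
    mutation_end: float = 0.02
    greedy_seed_fraction: float = 0.2
    stagnation_patience: int = 10
    two_opt_every: int = 5
    mutation_op: str = "inversion"  # or "swap"
    rng_seed: int = 0

    def __post_init__(self):
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if not (self.mutation_start >= self.mutation_end >= 0):
            raise ValueError("need mutation_start >= mutation_end >= 0")
        if not 0 <= self.greedy_seed_fraction <= 1:
            raise ValueError("greedy_seed_fraction must lie in [0, 1]")

    def with_overrides(self, **kwargs) -> "GAConfig":
        return replace(self, **kwargs)


#: ablation of the hybrid GA down to a plain textbook GA: random
#: initialization only, no 2-opt polish, constant mutation rate.
def plain_ga_config(base: GAConfig | None = None) -> GAConfig:
    base = base or GAConfig()
    return base.with_overrides(
        greedy_seed_fraction=0.0,
        two_opt_every=0,
        mutation_end=base.mutation_start,
    )


def dynamic_ga_params(n: int) -> tuple[int, int]:
    """Population size and generation budget as a function of scene size.

    N = clamp(4n, 20, 120), G = clamp(10n, 50, 400). Clamping keeps the
    GA's total work bounded by a constant times n^2.
    """
    if n < 1:
        raise PlannerError("n must be at least 1")
    pop = int(min(max(4 * n, 20), 120))
    gens = int(min(max(10 * n, 50), 400))
    return pop, gens


def mutation_rate(generation: int, cfg: GAConfig) -> float:
    """Linearly decaying mutation probability across generations."""
    g_max = cfg.max_generations
    if not 0 <= generation < g_max:
        raise PlannerError(f"generation {generation} outside [0, {g_max})")
    if g_max == 1:
        return cfg.mutation_start
    frac = generation / (g_max - 1)
    return cfg.mutation_start - (cfg.mutation_start - cfg.mutation_end) * frac


def _closed_lengths(pop: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Closed tour lengths for a whole population, vectorized."""
    return dist[pop, np.roll(pop, -1, axis=1)].sum(axis=1)


def _order_crossover(p1: np.ndarray, p2: np.ndarray, i: int, j: int) -> np.ndarray:
    """OX: copy p1[i..j], fill the rest cyclically from p2's order."""
    n = len(p1)
    child = np.empty(n, dtype=p1.dtype)
    child[i : j + 1] = p1[i : j + 1]
    hold = np.zeros(n, dtype=bool)
    hold[p1[i : j + 1]] = True
    rest = p2[~hold[p2]]
    slots = np.concatenate([np.arange(j + 1, n), np.arange(0, i)])
    child[slots] = rest
    return child


def _mutate(order: np.ndarray, rng: np.random.Generator, op: str) -> None:
    n = len(order)
    i, j = np.sort(rng.integers(0, n, size=2))
    if i == j:
        return
    if op == "inversion":
        order[i : j + 1] = order[i : j + 1][::-1]
    elif op == "swap":
        order[i], order[j] = order[j], order[i]
    else:
        raise PlannerError(f"unknown mutation op {op!r}")


def _initial_population(
    pts: np.ndarray,
    dist: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    seed_orders: Sequence[Sequence[int]] | None,
) -> np.ndarray:
    n = len(pts)
    N = cfg.population_size
    members: list[np.ndarray] = []
    if seed_orders:
        for order in seed_orders:
            members.append(_check_permutation(order, n))
    n_greedy = int(round(cfg.greedy_seed_fraction * N))
    if n_greedy > 0:
        starts = rng.permutation(n)[: min(n_greedy, n)]
        for s in starts:
            members.append(np.asarray(nearest_neighbor_tour(pts, int(s)).order))
    while len(members) < N:
        members.append(rng.permutation(n))
    return np.stack(members[:N])


def ga_tour(
    points,
    cfg: GAConfig | None = None,
    seed_orders: Sequence[Sequence[int]] | None = None,
) -> Tour:
    """Hybrid genetic algorithm over closed tours.

    The initial population mixes nearest-neighbor constructions from
    random distinct starts (a ``greedy_seed_fraction`` of the
    population), any caller-supplied ``seed_orders`` (the adaptive
    pipeline injects the reciprocating and nearest-neighbor tours,
    which guarantees the result never exceeds them), and uniform random
    permutations. Each generation keeps ``elite_count`` best members
    unchanged, fills the rest via tournament parent selection, order
    crossover and inversion mutation at the decayed rate, and every
    ``two_opt_every`` generations polishes the incumbent with 2-opt.
    Evolution stops at the generation budget or after
    ``stagnation_patience`` generations without improvement.

    The best closed length is non-increasing across generations
    (elitism), and the run is deterministic for a fixed ``rng_seed``.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise PlannerError("ga_tour requires at least two points")
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    dist = squareform(pdist(pts))

    pop = _initial_population(pts, dist, cfg, rng, seed_orders)
    lengths = _closed_lengths(pop, dist)
    N = cfg.population_size
    use_two_opt = cfg.two_opt_every > 0

    best_idx = int(np.argmin(lengths))
    best_order = pop[best_idx].copy()
    best_len = float(lengths[best_idx])
    stagnant = 0

    for g in range(cfg.max_generations):
        p_mut = mutation_rate(g, cfg)
        elite = np.argsort(lengths, kind="stable")[: cfg.elite_count]
        children = [pop[e].copy() for e in elite]

        n_off = N - cfg.elite_count
        # tournament parent selection, two parents per offspring
        cand = rng.integers(0, N, size=(n_off, 2, cfg.tournament_size))
        winners = cand[
            np.arange(n_off)[:, None],
            np.arange(2)[None, :],
            np.argmin(lengths[cand], axis=2),
        ]
        do_cross = rng.random(n_off) < cfg.crossover_rate
        cuts = np.sort(rng.integers(0, n, size=(n_off, 2)), axis=1)
        do_mut = rng.random(n_off) < p_mut
        for k in range(n_off):
            p1, p2 = pop[winners[k, 0]], pop[winners[k, 1]]
            if do_cross[k]:
                child = _order_crossover(p1, p2, int(cuts[k, 0]), int(cuts[k, 1]))
            else:
                child = p1.copy()
            if do_mut[k]:
                _mutate(child, rng, cfg.mutation_op)
            children.append(child)

        pop = np.stack(children)
        lengths = _closed_lengths(pop, dist)

        if use_two_opt and (g + 1) % cfg.two_opt_every == 0:
            i_best = int(np.argmin(lengths))
            pop[i_best] = _two_opt_order(pop[i_best], dist)
            lengths[i_best] = _closed_lengths(pop[None, i_best], dist)[0]

        gen_best = float(lengths.min())
        if gen_best < best_len - _STAGNATION_TOL:
            best_len = gen_best
            best_order = pop[int(np.argmin(lengths))].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.stagnation_patience:
                break

    if use_two_opt:
        best_order = _two_opt_order(best_order, dist)
    return make_tour(best_order, pts)


# ---------------------------------------------------------------------------
# ant-system baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACOConfig:
    """Standard ant-system parameters (benchmark baseline).

    ``ant_count`` of ``None`` means one ant per waypoint.
    """

    ant_count: int | None = None
    iterations: int = 100
    alpha: float = 1.0
    beta: float = 3.0
    evaporation: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation must lie in (0, 1)")
        if self.iterations < 1 or (self.ant_count is not None and self.ant_count < 1):
            raise ValueError("counts must be positive")

    def with_overrides(self, **kwargs) -> "ACOConfig":
        return replace(self, **kwargs)


def aco_tour(points, cfg: ACOConfig | None = None) -> Tour:
    """Ant-system TSP baseline: probabilistic tour construction with
    pheromone^alpha * (1/d)^beta transition weights, global evaporation
    and 1/length deposits; returns the best-so-far closed tour.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise PlannerError("aco_tour requires at least two points")
    cfg = cfg or ACOConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    ants = cfg.ant_count or n

    dist = squareform(pdist(pts))
    with np.errstate(divide="ignore"):
        heur = np.where(dist > 0, 1.0 / np.maximum(dist, 1e-12), 0.0)
    np.fill_diagonal(heur, 0.0)
    nn_len = nearest_neighbor_tour(pts, 0).length
    tau = np.full((n, n), 1.0 / max(n * max(nn_len, 1e-12), 1e-12))

    best_order: np.ndarray | None = None
    best_len = np.inf
    for _ in range(cfg.iterations):
        weight = tau**cfg.alpha * heur**cfg.beta
        current = rng.integers(0, n, size=ants)
        tours = np.empty((ants, n), dtype=int)
        tours[:, 0] = current
        visited = np.zeros((ants, n), dtype=bool)
        visited[np.arange(ants), current] = True
        for step in range(1, n):
            w = weight[current].copy()
            w[visited] = 0.0
            totals = w.sum(axis=1)
            # degenerate rows (all-zero weights) fall back to uniform
            bad = totals <= 0
            if bad.any():
                w[bad] = ~visited[bad]
                totals = w.sum(axis=1)
            cum = np.cumsum(w, axis=1)
            r = rng.random(ants) * totals
            nxt = (cum < r[:, None]).sum(axis=1)
            nxt = np.minimum(nxt, n - 1)
            tours[:, step] = nxt
            visited[np.arange(ants), nxt] = True
            current = nxt
        lengths = _closed_lengths(tours, dist)
        i = int(np.argmin(lengths))
        if lengths[i] < best_len - _STAGNATION_TOL:
            best_len = float(lengths[i])
            best_order = tours[i].copy()
        tau *= 1.0 - cfg.evaporation
        a = tours
        b = np.roll(tours, -1, axis=1)
        deposits = 1.0 / lengths
        np.add.at(tau, (a.ravel(), b.ravel()), np.repeat(deposits, n))
        np.add.at(tau, (b.ravel(), a.ravel()), np.repeat(deposits, n))
    assert best_order is not None
    return make_tour(best_order, pts)


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------

def brute_force_optimal(points, max_n: int = 9) -> Tour:
    """Exact minimum closed tour by enumerating (n-1)!/2 orders.

    City 0 is fixed and reflections are skipped. Guarded to small n;
    intended as a test oracle, not a planner.
    """
    pts = _as_points(points)
    n = len(pts)
    if not 2 <= n <= max_n:
        raise PlannerError(f"brute force supports 2 <= n <= {max_n}, got {n}")
    dist = squareform(pdist(pts))
    best_order = None
    best_len = np.inf
    for perm in itertools.permutations(range(1, n)):
        if n > 2 and perm[0] > perm[-1]:
            continue  # reflection of an already-visited order
        order = (0,) + perm
        length = dist[order, np.roll(order, -1)].sum()
        if length < best_len:
            best_len = float(length)
            best_order = order
    return make_tour(best_order, pts)
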