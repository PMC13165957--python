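"""End-to-end adaptive planning and the benchmark harness.

:func:`rose_plan` wires detections through the complexity gate to the
selected planner. When the gate picks the genetic planner, the GA's
initial population is seeded with both the reciprocating tour and the
nearest-neighbor tour; elitism then guarantees the adaptive planner
never returns a longer closed tour than either seed (dominance).

:func:`run_benchmark` mirrors a four-way comparison design:
reciprocating traversal, ant-colony optimization, a plain genetic
algorithm (random initialization, constant mutation, no 2-opt), and
the adaptive planner, all on identical scenes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import complexity, planners
from .complexity import ComplexityReport, GateConfig, GENETIC, RECIPROCATING
from .planners import ACOConfig, GAConfig, Tour
from .scene_io import Scene

STRATEGIES = ("reciprocating", "aco", "ga_plain", "rose")


@dataclass(frozen=True)
class PlanResult:
    """A planned picking tour with full provenance."""

    category: str
    report: ComplexityReport
    tour: Tour
    planner_used: str
    ga_params_used: GAConfig | None
    runtime: float  # seconds, informational only
    rng_seed: int


@dataclass(frozen=True)
class BenchmarkRow:
    """Per-strategy aggregate over a scene set."""

    strategy: str
    n_scenes: int
    n_bud: int
    n_bloom: int
    mean_runtime: float
    mean_closed_length: float


def rose_plan(
    scene: Scene,
    category: str = "combined",
    gate_cfg: GateConfig | None = None,
    ga_cfg: GAConfig | None = None,
    seed: int = 0,
) -> PlanResult:
    """Adaptive planning for one scene and category.

    Computes the complexity report, selects the planner, and plans the
    tour. With the genetic planner, population size and generation
    budget come from :func:`planners.dynamic_ga_params` unless an
    explicit ``ga_cfg`` is given, and the reciprocating and
    nearest-neighbor tours are injected into the initial population.
    Fully reproducible from (scene, configs, seed).
    """
    gate_cfg = gate_cfg or GateConfig()
    pts = scene.points(category)
    n = len(pts)
    if n == 0:
        raise complexity.EmptySceneError(
            f"scene has no {category!r} waypoints to plan"
        )
    t0 = time.perf_counter()
    report = complexity.evaluate_scene(
        pts, scene.image_width, scene.image_height, category, gate_cfg
    )
    ga_used: GAConfig | None = None
    if n == 1:
        tour = planners.make_tour([0], pts)
    elif report.selected == RECIPROCATING:
        tour = planners.reciprocating_tour(pts)
    else:
        if ga_cfg is None:
            pop, gens = planners.dynamic_ga_params(n)
            ga_used = GAConfig(population_size=pop, max_generations=gens,
                               rng_seed=seed)
        else:
            ga_used = ga_cfg.with_overrides(rng_seed=seed)
        seeds = [
            planners.reciprocating_tour(pts).order,
            planners.nearest_neighbor_tour(pts).order,
        ]
        tour = planners.ga_tour(pts, ga_used, seed_orders=seeds)
    runtime = time.perf_counter() - t0
    return PlanResult(
        category=category,
        report=report,
        tour=tour,
        planner_used=report.selected,
        ga_params_used=ga_used,
        runtime=runtime,
        rng_seed=seed,
    )


def _plan_with_strategy(
    strategy: str,
    scene: Scene,
    category: str,
    gate_cfg: GateConfig,
    aco_cfg: ACOConfig,
    seed: int,
) -> tuple[Tour, str, float]:
    pts = scene.points(category)
    n = len(pts)
    t0 = time.perf_counter()
    if n == 1:
        tour, used = planners.make_tour([0], pts), strategy
    elif strategy == "reciprocating":
        tour, used = planners.reciprocating_tour(pts), strategy
    elif strategy == "aco":
        tour = planners.aco_tour(pts, aco_cfg.with_overrides(rng_seed=seed))
        used = strategy
    elif strategy == "ga_plain":
        pop, gens = planners.dynamic_ga_params(n)
        cfg = planners.plain_ga_config(
            GAConfig(population_size=pop, max_generations=gens, rng_seed=seed)
        )
        tour, used = planners.ga_tour(pts, cfg), strategy
    elif strategy == "rose":
        result = rose_plan(scene, category, gate_cfg, seed=seed)
        tour, used = result.tour, f"rose/{result.planner_used}"
    else:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    return tour, used, time.perf_counter() - t0


def run_benchmark(
    scenes: Sequence[Scene],
    strategies: Iterable[str] = STRATEGIES,
    seed: int = 0,
    category: str = "combined",
    gate_cfg: GateConfig | None = None,
    aco_cfg: ACOConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every strategy on every scene.

    Returns ``(summary, per_scene)`` DataFrames: one aggregate row per
    strategy (identical detection-point totals across strategies, since
    all see the same scenes) and one audit row per scene x strategy.
    Deterministic for a fixed ``seed``: scene k is planned with child
    seed ``seed * 1009 + k`` under every strategy.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("need at least one scene")
    strategies = list(strategies)
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}; choose from {STRATEGIES}")
    gate_cfg = gate_cfg or GateConfig()
    aco_cfg = aco_cfg or ACOConfig()
    records = []
    for k, scene in enumerate(scenes):
        child_seed = (seed * 1009 + k) % (2**31)
        for strategy in strategies:
            if len(scene.points(category)) == 0:
                continue
            tour, used, dt = _plan_with_strategy(
                strategy, scene, category, gate_cfg, aco_cfg, child_seed
            )
            records.append(
                {
                    "scene": scene.scene_id or str(k),
                    "scene_index": k,
                    "strategy": strategy,
                    "planner_used": used,
                    "n_bloom": scene.count("bloom"),
                    "n_bud": scene.count("bud"),
                    "closed_length": tour.length,
                    "open_length": tour.open_length,
                    "runtime": dt,
                }
            )
    per_scene = pd.DataFrame.from_records(records)
    summary = (
        per_scene.groupby("strategy", sort=False)
        .agg(
            n_scenes=("scene", "size"),
            n_bud=("n_bud", "sum"),
            n_bloom=("n_bloom", "sum"),
            mean_runtime=("runtime", "mean"),
            mean_closed_length=("closed_length", "mean"),
        )
        .reset_index()
    )
    return summary, per_scene


def summary_rows(summary: pd.DataFrame) -> list[BenchmarkRow]:
    return [
        BenchmarkRow(
            strategy=r.strategy,
            n_scenes=int(r.n_scenes),
            n_bud=int(r.n_bud),
            n_bloom=int(r.n_bloom),
            mean_runtime=float(r.mean_runtime),
            mean_closed_length=float(r.mean_closed_length),
        )
        for r in summary.itertuples()
    ]


def render_path(scene: Scene, result: PlanResult, image=None, out_path=None):
    """Draw the planned tour: numbered waypoints, solid polyline, and a
    dashed closing edge, over the image (or a white canvas).

    Returns the matplotlib figure; writes a PNG when ``out_path`` is
    given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = scene.points(result.category)
    order = np.asarray(result.tour.order, dtype=int)
    if order.size != len(pts) or (order.size and order.max() >= len(pts)):
        raise ValueError("tour does not index this scene's waypoints")
    fig, ax = plt.subplots(figsize=(7, 7 * scene.image_height / scene.image_width))
    if image is not None:
        ax.imshow(np.asarray(image), extent=(0, scene.image_width,
                                             scene.image_height, 0))
    else:
        ax.set_facecolor("white")
    path = pts[order]
    ax.plot(path[:, 0], path[:, 1], "-", color="tab:blue", lw=1.5, zorder=2)
    if result.tour.closed and len(path) > 1:
        ax.plot([path[-1, 0], path[0, 0]], [path[-1, 1], path[0, 1]],
                "--", color="tab:blue", lw=1.2, zorder=2)
    ax.scatter(path[:, 0], path[:, 1], s=45, c="tab:red", zorder=3)
    for visit, (x, y) in enumerate(path):
        ax.annotate(str(visit + 1), (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    ax.set_xlim(0, scene.image_width)
    ax.set_ylim(scene.image_height, 0)  # y down, origin top-left
    ax.set_aspect("equal")
    ax.set_title(
        f"{result.planner_used} tour, closed length "
        f"{result.tour.length:.1f} px (n={len(pts)})"
    )
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
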