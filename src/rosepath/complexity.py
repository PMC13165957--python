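"""Scene-complexity scoring and the planner decision tree.

A scene is summarized by three statistics: the waypoint count n, a
target density rho, and the mean pairwise Euclidean distance d_bar.
Density and distance each pass through the saturating transform
x / (1 + x) and combine into a complexity score

    c = w_time * rho / (1 + rho) + w_distance * d / (1 + d)

with default weights 0.6 / 0.4, so c is dimensionless and bounded in
[0, 1). The decision tree then picks a planner:

    n < 3                 -> reciprocating (trivially small scene)
    n > 20                -> genetic       (always worth optimizing)
    otherwise             -> reciprocating if c <= 0.4 else genetic,
                             except bud scenes with rho > 0.5, which
                             force the genetic planner (dense buds are
                             where serpentine sweeps waste the most
                             travel).

Units: raw-pixel density (n / pixel area) would be ~1e-5 and raw-pixel
mean distance would saturate the transform at ~1, leaving the score
insensitive. Both statistics are therefore normalized before scoring:
rho counts targets per reference tile (default: 1/10 of the image
area, so a field scene of ~20 targets sits at rho ~ 2 and a sparse one
of ~4 at rho ~ 0.4, bracketing the 0.5 bud-override threshold), and
d_bar is divided by the image diagonal. Both normalizations are
configurable and reported in every ComplexityReport.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist

RECIPROCATING = "reciprocating"
GENETIC = "genetic"

Category = Literal["bloom", "bud", "combined"]


class EmptySceneError(ValueError):
    """Planning is undefined for a scene with no waypoints."""


@dataclass(frozen=True)
class GateConfig:
    """Weights, thresholds and normalization units of the decision gate.

    Parameters
    ----------
    w_time, w_distance
        Complexity-score weights for the density and distance terms;
        must sum to 1.
    n_low, n_high
        Count thresholds: below ``n_low`` the reciprocating planner is
        forced, above ``n_high`` the genetic planner is forced.
    c_threshold
        Complexity score at or below which the reciprocating planner is
        kept in the intermediate-count band.
    bud_density_threshold
        Density above which bud scenes are escalated to the genetic
        planner regardless of c.
    density_ref_fraction
        Size of the density reference tile as a fraction of the image
        area; rho = targets per reference tile (default 0.1, i.e.
        rho = n/10). ``density_ref_area`` (absolute pixels^2)
        overrides it when set.
    distance_norm
        ``"diagonal"`` divides d_bar by the image diagonal before
        scoring; ``"none"`` feeds raw pixels to the saturating term.
    pair_metric
        ``"all_pairs"`` (mean over all unordered pairs, the default) or
        ``"nearest_neighbor"`` (mean nearest-neighbor distance).
    """

    w_time: float = 0.6
    w_distance: float = 0.4
    n_low: int = 3
    n_high: int = 20
    c_threshold: float = 0.4
    bud_density_threshold: float = 0.5
    density_ref_fraction: float = 0.1
    density_ref_area: float | None = None
    distance_norm: Literal["diagonal", "none"] = "diagonal"
    pair_metric: Literal["all_pairs", "nearest_neighbor"] = "all_pairs"

    def __post_init__(self):
        if not np.isclose(self.w_time + self.w_distance, 1.0):
            raise ValueError("w_time + w_distance must equal 1")
        for name in ("n_low", "n_high", "c_threshold", "bud_density_threshold",
                     "density_ref_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def ref_area(self, image_area: float) -> float:
        if self.density_ref_area is not None:
            return self.density_ref_area
        return image_area * self.density_ref_fraction

    def with_overrides(self, **kwargs) -> "GateConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ComplexityReport:
    """Scene statistics, complexity score and the selected planner."""

    n: int
    rho: float
    d_bar: float
    d_bar_normalized: float
    c: float
    selected: str
    density_ref_area: float


def complexity_score(rho: float, d_bar: float, cfg: GateConfig | None = None) -> float:
    """Weighted sum of saturating transforms of density and distance.

    ``d_bar`` must already be on the configured normalized scale.
    Bounded in [0, 1); strictly increasing in each argument.
    """
    cfg = cfg or GateConfig()
    if rho < 0 or d_bar < 0:
        raise ValueError("rho and d_bar must be non-negative")
    return cfg.w_time * rho / (1.0 + rho) + cfg.w_distance * d_bar / (1.0 + d_bar)


def mean_pairwise_distance(points: np.ndarray, metric: str = "all_pairs") -> float:
    """Mean Euclidean distance over all unordered pairs (0 when n < 2).

    ``metric="nearest_neighbor"`` averages each point's nearest-neighbor
    distance instead.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    d = pdist(pts)
    if metric == "all_pairs":
        return float(d.mean())
    if metric == "nearest_neighbor":
        from scipy.spatial.distance import squareform

        m = squareform(d)
        np.fill_diagonal(m, np.inf)
        return float(m.min(axis=1).mean())
    raise ValueError(f"unknown pair metric {metric!r}")


def scene_stats(
    points: np.ndarray, area: float, cfg: GateConfig | None = None
) -> tuple[int, float, float]:
    """Return (n, rho, d_bar) for a point set in an image of ``area`` px^2.

    rho is targets per density reference tile; d_bar is the raw-pixel
    mean pairwise distance (normalization happens at scoring time).
    """
    cfg = cfg or GateConfig()
    if area <= 0:
        raise ValueError("area must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    rho = n / (area / cfg.ref_area(area))
    d_bar = mean_pairwise_distance(pts, cfg.pair_metric)
    return n, rho, d_bar


def select_algorithm(
    n: int, c: float, rho: float, category: Category, cfg: GateConfig | None = None
) -> str:
    """Decision tree mapping (n, c, rho, category) to a planner name.

    Boundary semantics are strict/non-strict exactly as documented on
    :class:`GateConfig`: ``n < n_low``, ``n > n_high``, ``c <=
    c_threshold``, ``rho > bud_density_threshold``.
    """
    cfg = cfg or GateConfig()
    if n == 0:
        raise EmptySceneError("cannot select a planner for an empty scene")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n < cfg.n_low:
        return RECIPROCATING
    if n > cfg.n_high:
        return GENETIC
    initial = RECIPROCATING if c <= cfg.c_threshold else GENETIC
    if category == "bud" and rho > cfg.bud_density_threshold:
        return GENETIC
    return initial


def evaluate_scene(
    points: np.ndarray,
    image_width: float,
    image_height: float,
    category: Category,
    cfg: GateConfig | None = None,
) -> ComplexityReport:
    """Compute scene statistics, the score, and the planner selection."""
    cfg = cfg or GateConfig()
    area = image_width * image_height
    n, rho, d_bar = scene_stats(points, area, cfg)
    if cfg.distance_norm == "diagonal":
        d_norm = d_bar / float(np.hypot(image_width, image_height))
    else:
        d_norm = d_bar
    c = complexity_score(rho, d_norm, cfg)
    selected = select_algorithm(n, c, rho, category, cfg)
    return ComplexityReport(
        n=n, rho=rho, d_bar=d_bar, d_bar_normalized=d_norm, c=c,
        selected=selected, density_ref_area=cfg.ref_area(area),
    )
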