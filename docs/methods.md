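# Methods

## Problem setting

Each camera frame yields a set of class-labelled bounding boxes
(`bloom` / `bud`); box centers are the picking waypoints. The planner
minimizes the closed Euclidean tour length over the waypoints of one
category (blooms and buds are harvested separately by default; a
`combined` mode merges them). All geometry is in pixel units, origin
top-left, x right, y down, with continuous (unrounded) centers.
Confidence scores, when present in JSON inputs, are carried through
but never used for planning: every detected center is a target.
Coincident duplicate detections are retained, and all planners
tolerate the resulting zero-length edges.

## Image rescaling

Frames above a pixel budget (default 1 MP = 1,048,576 px²) are shrunk
by `factor = sqrt(budget / pixel_count)`; raster resampling uses the
Lanczos filter. The record keeps the original dimensions so planned
paths map exactly back to original pixel coordinates
(`to_working`/`to_original` are exact inverses; working dimensions are
floored so a rescaled image is itself budget-compliant and the
operation is idempotent).

## Complexity gate

Scene statistics: n (count), ρ (density), d̄ (mean Euclidean distance
over all unordered pairs; a nearest-neighbor variant is selectable).
The score is

    c = w_t · ρ/(1+ρ) + w_d · d̄ₙ/(1+d̄ₙ),  w_t = 0.6, w_d = 0.4,

bounded in [0, 1) and strictly increasing in both arguments. Decision
tree (boundary operators literal): n < 3 → reciprocating; n > 20 →
genetic; otherwise reciprocating iff c ≤ 0.4, except bud scenes with
ρ > 0.5, which force the genetic planner.

**Normalization.** Raw-pixel units would make the score degenerate:
ρ = n/area ≈ 10⁻⁵ and d̄/(1+d̄) ≈ 1 for any real frame. Two
normalizations fix this, both configurable and reported in every
`ComplexityReport`:

- ρ counts targets per *reference tile*, default one tenth of the
  image area (ρ = n/10). A typical field scene of ~15–20 targets then
  sits at ρ ≈ 1.5–2 and a sparse one of ~4 at ρ ≈ 0.4, so the 0.5
  bud-override threshold actually discriminates between them. (A
  smaller 1%-tile variant was considered and rejected: it puts every
  realistic scene at ρ ≈ 0.15, leaving the override and most of the
  c-range unreachable, and collapses the adaptive planner to
  always-serpentine — visible in its runtime profile, which should be
  dominated by GA calls on ordinary field scenes.)
- d̄ is divided by the image diagonal before entering the score, so
  d̄ₙ ∈ [0, 1] measures spread relative to the frame.

Whether "area" means the full frame or a region of interest is an
open modelling question; the full frame is used.

## Planners

**Reciprocating (boustrophedon).** Points are bucketed into horizontal
bands (default band height: y-span / ⌈√n⌉, roughly square bands),
bands visited top to bottom, each sorted by x with alternating sweep
direction between successive non-empty bands. Both open and closed
lengths are reported; the closed length is used for cross-planner
comparison since the objective closes the loop.

**Nearest neighbor.** Greedy construction; distance ties break toward
the lowest index, making it deterministic.

**2-opt.** First-improvement segment reversals, sweeping until no
improving move exists (improvement threshold 10⁻⁹ to avoid
float-churn). Local optima contain no properly crossing edge pair on
Euclidean instances. First-improvement was chosen over best-improvement
for speed; the terminal state is locally optimal either way.

**Hybrid GA.** Order-based GA on closed tours, fitness 1/length:

| parameter | default | notes |
|---|---|---|
| population N | clamp(4n, 20, 120) | adaptive schedule |
| generations G | clamp(10n, 50, 400) | adaptive schedule |
| elite count | 2 | copied unchanged → monotone best |
| tournament size | 3 | parent selection |
| crossover rate | 0.9 | order crossover (OX) |
| mutation | 0.20 → 0.02 | linear decay over G; inversion operator |
| greedy seed fraction | 0.2 | NN tours from random distinct starts |
| 2-opt cadence | every 5 generations | on the incumbent, plus a final polish |
| stagnation patience | 10 | stop after 10 generations without improvement |

OX is the standard permutation-safe crossover; inversion mutation
couples naturally with 2-opt neighborhoods (swap mutation is available
via config). The clamps keep total work O(G·N·n) ⊆ O(n²). All
randomness flows from a single seeded NumPy generator per call; every
result is bit-reproducible from its seed. The adaptive pipeline
injects the reciprocating and nearest-neighbor tours into the initial
population, so elitism guarantees the returned tour is never longer
than either — the dominance invariant checked per-scene in the tests.

**Plain-GA baseline** (`ga_plain`): the same machinery ablated to a
textbook GA — random initialization only, constant mutation rate
(0.20), no 2-opt — representing a conventional genetic-algorithm
comparator. **Ant system**: standard construction with
pheromone^α · (1/d)^β weights (α = 1, β = 3), evaporation 0.5, one ant
per waypoint, deposits 1/length; a quality-strong but slow baseline.
**Brute force**: exact enumeration of (n−1)!/2 closed orders, n ≤ 9,
used only as a test oracle.

Whether the field objective is the open or the closed path is
ambiguous; both lengths are always reported and the closed loop is the
documented optimization target. For open-path reporting the start is
the waypoint closest to the image origin — irrelevant to closed
lengths.

## Synthetic scenes

The generator emulates the two spatial signatures of rose fields:
blooms as a uniform Poisson process, buds as a Thomas cluster process
(Poisson parents ~ mean 3 stems, Gaussian offspring, sd 35 px), with a
minimum-separation rejection step (8 px) standing in for physical
flower extent. Default counts are calibrated to a one-season field
campaign: Poisson means 14.6 buds and 4.9 blooms per frame (the
per-image averages of ~4.2k bud and ~1.4k bloom detections over 288
validation images), at 1040×780 px working frames. Scenes are
guaranteed non-empty. Named presets (`sparse`, `dense`,
`clustered_buds`, `large_scene`) span n ≈ 2–200 and every gate branch;
the Clark–Evans index of generated buds is < 1 (clustered) while
blooms sit near 1 (random).

`benchmark_suite` draws a default-majority mixture (~73% calibrated
default scenes, 16% sparse, 7% clustered, 4% dense, plus four scenes
pinned to the gate's count boundaries n = 2, 3, 20, 21) so that the
suite's expected detection totals reproduce the campaign's. The
`large_scene` stress preset is deliberately outside this mixture: an
80-target 2080×1560 frame has no counterpart in a campaign averaging
~20 targets per image.

**What the generator does not model:** illumination, occlusion and
detector error (missed or spurious boxes), perspective distortion, and
any correlation between bloom and bud positions. Passing benchmarks on
these scenes therefore demonstrates planner behavior under the assumed
spatial statistics, not detection robustness on real imagery.

## Benchmark harness

`run_benchmark` plans identical scenes under each strategy
(reciprocating, ant system, plain GA, adaptive) with per-scene child
seeds, and aggregates mean runtime and mean closed length per
strategy; per-scene rows are returned for auditing. Runtimes are
recorded as information only — they are hardware-dependent and never
asserted against. Absolute mean lengths depend entirely on the scene
statistics above; only the qualitative ordering (adaptive < plain GA
< reciprocating, with zero per-scene dominance violations) is treated
as a reproducible claim. The acceptance script runs the three fast
strategies on the full 288-scene suite and adds the ant-colony
baseline on a 48-scene subset at 60 iterations, a problem size chosen
to keep its quadratic construction cost proportionate to the other
strategies.

## PConv accounting

Multiply–accumulates of the convolution proper: a k×k convolution on
c channels costs h·w·k²·c²; applied to only c_p = r·c channels (rest
pass-through, bias free) it costs h·w·k²·c_p², hence a speed-up of
1/r² independent of h, w, k — 16× at r = 1/4. This is the closed-form
arithmetic only; no network layers are implemented.

## Numerical choices and degenerate inputs

- Length comparisons (stagnation, dominance, 2-opt gain) use an
  absolute tolerance of 10⁻⁹.
- n = 1 scenes yield the trivial zero-length tour; n = 0 raises.
- Coincident points give zero-length edges everywhere; NN and argmin
  ties resolve to the lowest index.
- GA with `max_generations = 1` returns the start-rate mutation
  schedule endpoint.
- Seeds derived for child processes stay below 2³¹.

## Known limitations

Planning is purely 2-D in the image plane: no depth, no arm
kinematics, no obstacle or stem geometry. The gate's thresholds
(3, 20, 0.4, 0.5) and weights (0.6/0.4) are fixed domain defaults,
not fitted quantities; the density/distance normalizations are this
package's own declared choices where the field convention is
ambiguous. Absolute benchmark lengths are functions of the synthetic
scene statistics and are not comparable to lengths measured on any
particular real image set.
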