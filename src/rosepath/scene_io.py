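"""Detection input/output and coordinate handling.

Reads detector outputs (YOLO label files or JSON bounding-box lists),
extracts picking waypoints (box centers), and implements the
pixel-count-based dynamic rescaling used to keep working images below a
pixel budget, with exact back-mapping of planned coordinates to the
original frame.

Coordinate convention: pixel units, origin at the image top-left, x to
the right, y downward, continuous (centers are never rounded).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

BLOOM = "bloom"
BUD = "bud"
CLASSES = (BLOOM, BUD)

#: default mapping of YOLO integer class ids to growth states
DEFAULT_CLASS_MAP: Mapping[int, str] = {0: BLOOM, 1: BUD}

#: default working-image pixel budget (1 megapixel)
DEFAULT_PIXEL_BUDGET = 1_048_576


class SceneIOError(ValueError):
    """Base class for detection-input errors."""


class ParseError(SceneIOError):
    """A label line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class UnknownClassError(SceneIOError):
    """A class id in the label file is absent from the class map."""


@dataclass(frozen=True)
class Detection:
    """One class-labelled bounding box; its center is a picking waypoint."""

    class_label: str
    cx: float
    cy: float
    w: float
    h: float
    source_line: int
    score: float | None = None

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise UnknownClassError(f"unknown class label {self.class_label!r}")
        if self.w <= 0 or self.h <= 0:
            raise SceneIOError(
                f"line {self.source_line}: box extents must be positive "
                f"(got w={self.w}, h={self.h})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass
class Scene:
    """An image-sized workspace with its per-class picking waypoints.

    Waypoint lists preserve the input-file order. Coincident points are
    retained (no deduplication); downstream planners tolerate
    zero-length edges.
    """

    image_width: float
    image_height: float
    detections: list[Detection] = field(default_factory=list)
    scale_applied: float = 1.0
    scene_id: str | None = None

    def __post_init__(self):
        if self.image_width <= 0 or self.image_height <= 0:
            raise SceneIOError("image dimensions must be positive")

    @property
    def area(self) -> float:
        return self.image_width * self.image_height

    @property
    def diagonal(self) -> float:
        return math.hypot(self.image_width, self.image_height)

    def points(self, category: str) -> np.ndarray:
        """Waypoints of one category as an (n, 2) float array.

        ``category`` is ``"bloom"``, ``"bud"`` or ``"combined"``
        (blooms first, then buds, each in input order).
        """
        if category == "combined":
            dets = [d for d in self.detections if d.class_label == BLOOM] + [
                d for d in self.detections if d.class_label == BUD
            ]
        elif category in CLASSES:
            dets = [d for d in self.detections if d.class_label == category]
        else:
            raise SceneIOError(f"unknown category {category!r}")
        if not dets:
            return np.empty((0, 2), dtype=float)
        return np.array([[d.cx, d.cy] for d in dets], dtype=float)

    @property
    def points_bloom(self) -> np.ndarray:
        return self.points(BLOOM)

    @property
    def points_bud(self) -> np.ndarray:
        return self.points(BUD)

    def count(self, category: str) -> int:
        return len(self.points(category))

    def validate(self) -> None:
        """Check every waypoint lies inside the image bounds."""
        for d in self.detections:
            if not (0 <= d.cx <= self.image_width and 0 <= d.cy <= self.image_height):
                raise SceneIOError(
                    f"waypoint ({d.cx:.2f}, {d.cy:.2f}) outside "
                    f"{self.image_width}x{self.image_height} image"
                )


def load_yolo_labels(
    label_path,
    image_width: float,
    image_height: float,
    class_map: Mapping[int, str] | None = None,
) -> Scene:
    """Parse one YOLO label file into a :class:`Scene`.

    Each non-empty line is ``<class_id> <cx> <cy> <w> <h>`` with the
    last four fields normalized to [0, 1]; centers are denormalized as
    ``(cx * image_width, cy * image_height)``.
    """
    if image_width <= 0 or image_height <= 0:
        raise SceneIOError("image dimensions must be positive")
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    path = Path(label_path)
    detections: list[Detection] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(
                    path, line_no, f"expected 5 fields, got {len(fields)}"
                )
            try:
                cls = int(fields[0])
                cx, cy, w, h = (float(v) for v in fields[1:])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric field: {exc}") from exc
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not 0.0 <= v <= 1.0:
                    raise ParseError(
                        path, line_no, f"normalized field {name}={v} outside [0, 1]"
                    )
            if cls not in class_map:
                raise UnknownClassError(
                    f"{path}:{line_no}: class id {cls} not in class map {dict(class_map)}"
                )
            detections.append(
                Detection(
                    class_label=class_map[cls],
                    cx=cx * image_width,
                    cy=cy * image_height,
                    w=w * image_width,
                    h=h * image_height,
                    source_line=line_no,
                )
            )
    scene = Scene(image_width, image_height, detections, scene_id=path.stem)
    scene.validate()
    return scene


def write_yolo_labels(
    scene: Scene, label_path, class_map: Mapping[int, str] | None = None
) -> None:
    """Serialize a scene back to YOLO label format (inverse of loading)."""
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    inverse = {v: k for k, v in class_map.items()}
    w, h = scene.image_width, scene.image_height
    lines = []
    for d in scene.detections:
        lines.append(
            f"{inverse[d.class_label]} {d.cx / w:.9f} {d.cy / h:.9f} "
            f"{d.w / w:.9f} {d.h / h:.9f}"
        )
    Path(label_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_json_detections(json_path) -> Scene:
    """Load a JSON detection document.

    Schema::

        {"image_width": W, "image_height": H,
         "detections": [{"label": "bloom"|"bud",
                         "bbox": [x_min, y_min, x_max, y_max],
                         "score": 0.93}, ...]}

    ``score`` is optional; it is carried through but ignored by
    planning. Waypoints are box midpoints. Identical boxes yield
    coincident waypoints (no deduplication).
    """
    path = Path(json_path)
    doc = json.loads(path.read_text())
    for key in ("image_width", "image_height"):
        if key not in doc:
            raise SceneIOError(f"{path}: missing required field {key!r}")
    detections = []
    for i, rec in enumerate(doc.get("detections", [])):
        try:
            label = rec["label"]
            x0, y0, x1, y1 = (float(v) for v in rec["bbox"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SceneIOError(f"{path}: malformed detection record {i}: {exc}") from exc
        if x1 <= x0 or y1 <= y0:
            raise SceneIOError(
                f"{path}: detection {i}: degenerate bbox ({x0}, {y0}, {x1}, {y1})"
            )
        detections.append(
            Detection(
                class_label=label,
                cx=(x0 + x1) / 2.0,
                cy=(y0 + y1) / 2.0,
                w=x1 - x0,
                h=y1 - y0,
                source_line=i,
                score=rec.get("score"),
            )
        )
    scene = Scene(float(doc["image_width"]), float(doc["image_height"]), detections,
                  scene_id=path.stem)
    scene.validate()
    return scene


@dataclass(frozen=True)
class RescaleRecord:
    """Record of the pixel-count-based dynamic scaling step.

    When an image exceeds the pixel budget it is shrunk by
    ``factor = sqrt(budget / pixel_count)`` so the working image sits at
    the budget; the original dimensions are retained so planned paths
    can be calibrated back to original pixel coordinates.
    """

    original_dims: tuple[int, int]
    working_dims: tuple[int, int]
    factor: float
    pixel_budget: int

    def to_working(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) * self.factor

    def to_original(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) / self.factor


def rescale_for_processing(
    dims: tuple[int, int], pixel_budget: int = DEFAULT_PIXEL_BUDGET
) -> RescaleRecord:
    """Compute the dynamic-scaling factor for an image of ``dims``.

    Images at or under the budget pass through unchanged (factor 1.0);
    the operation is idempotent on already-compliant dimensions.
    """
    w, h = dims
    if w <= 0 or h <= 0 or pixel_budget <= 0:
        raise SceneIOError("dimensions and pixel budget must be positive")
    pixel_count = w * h
    if pixel_count <= pixel_budget:
        return RescaleRecord((w, h), (int(w), int(h)), 1.0, pixel_budget)
    factor = math.sqrt(pixel_budget / pixel_count)
    # floor keeps the working image at or under budget, so a rescaled
    # image passes through unchanged if rescaled again
    working = (max(int(w * factor), 1), max(int(h * factor), 1))
    return RescaleRecord((w, h), working, factor, pixel_budget)


def rescale_image(image, record: RescaleRecord):
    """Resample a PIL image to the working dimensions (Lanczos filter)."""
    from PIL import Image

    if record.factor == 1.0:
        return image
    return image.resize(record.working_dims, resample=Image.LANCZOS)
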