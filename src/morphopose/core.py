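"""Shared domain types: keypoints, annotated images, measurement records.

The ten canonical body-surface keypoints are ordered anatomically front to
back; sequence models consume them in exactly this order.  Coordinates may
be metric (metres, ground plane at y=0, y up) or pixel (origin top-left,
x right, y down, 0-based, pixel centres) — the container is agnostic, the
producing function documents which frame it emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

KEYPOINT_NAMES: tuple[str, ...] = (
    "body_length_anterior",
    "body_length_posterior",
    "body_height_top",
    "body_height_ground",
    "chest_girth_upper",
    "chest_girth_lower",
    "oblique_length_anterior",
    "oblique_length_posterior",
    "cannon_outer",
    "cannon_inner",
)

MEASUREMENT_FIELDS: tuple[str, ...] = (
    "body_length",
    "body_height",
    "oblique_body_length",
    "chest_girth",
    "cannon_circumference",
)

#: keypoint pairs whose Euclidean distances define the five named features
NAMED_PAIRS: dict[str, tuple[str, str]] = {
    "body_length": ("body_length_anterior", "body_length_posterior"),
    "body_height": ("body_height_top", "body_height_ground"),
    "oblique_body_length": ("oblique_length_anterior", "oblique_length_posterior"),
    "chest_girth": ("chest_girth_upper", "chest_girth_lower"),
    "cannon_circumference": ("cannon_outer", "cannon_inner"),
}

VIS_NOT_LABELED, VIS_OCCLUDED, VIS_VISIBLE = 0, 1, 2


class SchemaError(ValueError):
    """Annotation file does not match the canonical keypoint schema."""


class CalibrationError(ValueError):
    """Ruler information is missing or degenerate."""


@dataclass
class KeypointSet:
    """Ordered map of the 10 canonical names to (x, y, visibility)."""

    points: dict[str, tuple[float, float, int]]

    def __post_init__(self):
        missing = [n for n in KEYPOINT_NAMES if n not in self.points]
        extra = [n for n in self.points if n not in KEYPOINT_NAMES]
        if missing or extra:
            raise SchemaError(f"missing keypoints {missing}, unexpected {extra}")
        # canonical ordering regardless of insertion order
        self.points = {n: tuple(self.points[n]) for n in KEYPOINT_NAMES}

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "KeypointSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape == (len(KEYPOINT_NAMES), 2):
            arr = np.column_stack([arr, np.full(len(arr), VIS_VISIBLE)])
        if arr.shape != (len(KEYPOINT_NAMES), 3):
            raise SchemaError(f"expected (10, 2|3) array, got {arr.shape}")
        return cls({n: (float(x), float(y), int(v)) for n, (x, y, v) in zip(KEYPOINT_NAMES, arr)})

    def as_array(self, with_visibility: bool = True) -> np.ndarray:
        rows = [self.points[n] for n in KEYPOINT_NAMES]
        arr = np.asarray(rows, dtype=float)
        return arr if with_visibility else arr[:, :2]

    def __getitem__(self, name: str) -> tuple[float, float, int]:
        return self.points[name]

    def xy(self, name: str) -> np.ndarray:
        return np.asarray(self.points[name][:2], dtype=float)

    def visible(self, name: str) -> bool:
        return self.points[name][2] == VIS_VISIBLE

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.xy(a) - self.xy(b)))

    def replace(self, name: str, x: float, y: float, v: int | None = None) -> None:
        old = self.points[name]
        self.points[name] = (float(x), float(y), old[2] if v is None else int(v))


@dataclass
class AnnotatedImage:
    """One annotated side view: keypoints, body box, ruler, identity."""

    image_path: str
    image_size: tuple[int, int]  # (height, width) px
    keypoints: KeypointSet
    box: tuple[float, float, float, float]  # x1, y1, x2, y2 px
    ruler_endpoints: np.ndarray  # (2, 2) px
    ruler_length_m: float = 1.1
    individual_id: str = ""
    view_index: int = 0
    contour: np.ndarray | None = None  # optional (K, 2) body polygon, px

    def __post_init__(self):
        self.ruler_endpoints = np.asarray(self.ruler_endpoints, dtype=float).reshape(2, 2)
        if self.ruler_length_m <= 0:
            raise CalibrationError("ruler length must be positive")
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class MeasurementRecord:
    """The five conformation measurements (cm) for one individual."""

    body_length: float
    body_height: float
    oblique_body_length: float
    chest_girth: float
    cannon_circumference: float
    body_weight: float | None = None
    individual_id: str = ""

    def validate(self) -> "MeasurementRecord":
        vals = self.as_array()
        if not np.all(vals > 0):
            raise ValueError(f"measurements must be strictly positive: {vals}")
        if not self.chest_girth > self.cannon_circumference:
            raise ValueError("chest girth must exceed cannon circumference")
        if self.oblique_body_length < 0.8 * self.body_length:
            raise ValueError("oblique body length below 0.8 x body length")
        return self

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, f) for f in MEASUREMENT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float], individual_id: str = "") -> "MeasurementRecord":
        vals = list(arr)
        return cls(*[float(v) for v in vals[:5]], individual_id=individual_id)
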