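"""Annotation I/O, keypoint-consistent augmentation and ID-based splitting.

Formats
-------
* Labelme-style JSON: a ``shapes`` list with ``point`` entries for the ten
  canonical keypoints, an optional ``polygon`` body contour, and a ``line``
  labelled ``ruler_1.1m`` for the scale reference.
* Pose-label text: one line per image,
  ``0 cx cy w h x1 y1 v1 ... x10 y10 v10``, all coordinates normalised to
  [0, 1] by image width/height (class fixed to 0 — single animal class).

Augmentation applies one similarity/affine map to pixels, keypoints, box and
ruler endpoints alike, so ruler calibration stays valid on augmented copies.
The dataset split operates on individual IDs, never on images, so no
individual's views can leak across subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from .core import (
    KEYPOINT_NAMES,
    VIS_NOT_LABELED,
    VIS_VISIBLE,
    AnnotatedImage,
    CalibrationError,
    KeypointSet,
    SchemaError,
)

RULER_LABEL = "ruler_1.1m"
CONTOUR_LABEL = "animal"


class SplitError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Labelme-style JSON
# ---------------------------------------------------------------------------


def write_labelme(ann: AnnotatedImage, json_path) -> None:
    shapes = []
    if ann.contour is not None:
        shapes.append(
            {
                "label": CONTOUR_LABEL,
                "points": np.asarray(ann.contour, dtype=float).round(2).tolist(),
                "shape_type": "polygon",
            }
        )
    for name in KEYPOINT_NAMES:
        x, y, v = ann.keypoints[name]
        shapes.append(
            {"label": name, "points": [[float(x), float(y)]], "shape_type": "point", "visibility": int(v)}
        )
    shapes.append(
        {
            "label": RULER_LABEL,
            "points": np.asarray(ann.ruler_endpoints, dtype=float).tolist(),
            "shape_type": "line",
            "ruler_length_m": float(ann.ruler_length_m),
        }
    )
    payload = {
        "version": "5.0.0",
        "imagePath": str(ann.image_path),
        "imageHeight": int(ann.image_size[0]),
        "imageWidth": int(ann.image_size[1]),
        "individual_id": ann.individual_id,
        "view_index": int(ann.view_index),
        "shapes": shapes,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))


def read_labelme(json_path) -> AnnotatedImage:
    """Parse one annotation file; canonical keypoint order is enforced
    regardless of the order of ``shapes`` entries."""
    path = Path(json_path)
    data = json.loads(path.read_text())
    points: dict[str, tuple[float, float, int]] = {}
    duplicates: list[str] = []
    ruler = None
    ruler_length = 1.1
    contour = None
    for shape in data.get("shapes", []):
        label, stype = shape.get("label", ""), shape.get("shape_type", "")
        if stype == "point" and label in KEYPOINT_NAMES:
            if label in points:
                duplicates.append(label)
            (x, y), = shape["points"]
            points[label] = (float(x), float(y), int(shape.get("visibility", VIS_VISIBLE)))
        elif stype == "line" and label.startswith("ruler"):
            ruler = np.asarray(shape["points"], dtype=float)
            ruler_length = float(shape.get("ruler_length_m", 1.1))
        elif stype == "polygon" and label == CONTOUR_LABEL:
            contour = np.asarray(shape["points"], dtype=float)
    missing = [n for n in KEYPOINT_NAMES if n not in points]
    if missing or duplicates:
        raise SchemaError(
            f"{path.name}: missing keypoint labels {missing}, duplicated {duplicates}"
        )
    if ruler is None or ruler.shape != (2, 2):
        raise CalibrationError(f"{path.name}: no ruler line found")
    kps = KeypointSet(points)
    h, w = int(data["imageHeight"]), int(data["imageWidth"])
    if contour is not None:
        box = _box_from_polygon(contour)
    else:
        box = _box_from_keypoints(kps, (h, w))
    return AnnotatedImage(
        image_path=data.get("imagePath", ""),
        image_size=(h, w),
        keypoints=kps,
        box=box,
        ruler_endpoints=ruler,
        ruler_length_m=ruler_length,
        individual_id=str(data.get("individual_id", "")),
        view_index=int(data.get("view_index", 0)),
        contour=contour,
    )


def _box_from_polygon(poly: np.ndarray) -> tuple[float, float, float, float]:
    return (float(poly[:, 0].min()), float(poly[:, 1].min()), float(poly[:, 0].max()), float(poly[:, 1].max()))


def _box_from_keypoints(kps: KeypointSet, image_size) -> tuple[float, float, float, float]:
    """Keypoint extremes plus a 5% margin, clipped to the image."""
    arr = kps.as_array()
    vis = arr[arr[:, 2] > 0, :2]
    if len(vis) == 0:
        raise SchemaError("no visible keypoints to derive a box from")
    x1, y1 = vis.min(axis=0)
    x2, y2 = vis.max(axis=0)
    mx, my = 0.05 * (x2 - x1), 0.05 * (y2 - y1)
    h, w = image_size
    return (
        float(max(x1 - mx, 0.0)),
        float(max(y1 - my, 0.0)),
        float(min(x2 + mx, w)),
        float(min(y2 + my, h)),
    )


# ---------------------------------------------------------------------------
# pose-label text dialect
# ---------------------------------------------------------------------------


def to_pose_label(ann: AnnotatedImage) -> str:
    """``0 cx cy w h x1 y1 v1 ... x10 y10 v10`` normalised to [0, 1]."""
    h, w = ann.image_size
    x1, y1, x2, y2 = ann.box
    coords = [((x1 + x2) / 2) / w, ((y1 + y2) / 2) / h, (x2 - x1) / w, (y2 - y1) / h]
    tol = 1e-6
    fields = []
    for val in coords:
        if not (-tol <= val <= 1 + tol):
            raise ConsistencyError(f"normalised value {val:.6f} outside [0, 1]")
        fields.append(f"{min(max(val, 0.0), 1.0):.6f}")
    for name in KEYPOINT_NAMES:
        x, y, v = ann.keypoints[name]
        for val in (x / w, y / h):
            if not (-tol <= val <= 1 + tol):
                raise ConsistencyError(f"normalised value {val:.6f} outside [0, 1] for {name}")
            fields.append(f"{min(max(val, 0.0), 1.0):.6f}")
        fields.append(f"{float(v):.6f}")
    return "0 " + " ".join(fields)


def parse_pose_label(line: str, image_size) -> tuple[tuple, np.ndarray]:
    """Inverse of :func:`to_pose_label`: (box xyxy px, (10, 3) keypoints px)."""
    parts = [float(p) for p in line.split()]
    if len(parts) != 5 + 3 * len(KEYPOINT_NAMES):
        raise ValueError(f"expected {5 + 3 * len(KEYPOINT_NAMES)} fields, got {len(parts)}")
    h, w = image_size
    _, cx, cy, bw, bh = parts[:5]
    box = ((cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h)
    kps = np.asarray(parts[5:], dtype=float).reshape(-1, 3)
    kps[:, 0] *= w
    kps[:, 1] *= h
    return box, kps


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentPolicy:
    """Training-time augmentation ranges (flip / scale / rotate / translate /
    additive Gaussian pixel noise), plus the number of augmented copies per
    original image when expanding a training set."""

    hflip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)
    rotate_deg: float = 15.0
    translate_frac: float = 0.10
    gauss_noise_sd: float = 5.0  # in 0..255 intensity units
    multiplicity: int = 3

    def validate(self) -> "AugmentPolicy":
        if not 0 <= self.hflip_prob <= 1:
            raise ValueError("hflip_prob must lie in [0, 1]")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ValueError("invalid scale range")
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be >= 0")
        return self

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(hflip_prob=0.0, scale_range=(1.0, 1.0), rotate_deg=0.0, translate_frac=0.0, gauss_noise_sd=0.0, multiplicity=0)


def _apply_points(mat: np.ndarray, pts: np.ndarray) -> np.ndarray:
    homog = np.column_stack([pts, np.ones(len(pts))])
    return (homog @ mat.T)[:, :2]


def augment(
    ann: AnnotatedImage,
    image: np.ndarray,
    policy: AugmentPolicy,
    rng_seed: int = 0,
) -> tuple[np.ndarray, AnnotatedImage]:
    """One sampled augmentation; the identical geometric map is applied to
    pixels, keypoints, box and ruler.  Keypoints leaving the frame are marked
    not-labeled.  Horizontal flip maps x -> W-1-x and keeps keypoint
    identities (the ten side-view points have no left/right pairs; a flip is
    the animal facing the other way)."""
    policy.validate()
    rng = np.random.default_rng(rng_seed)
    h, w = ann.image_size
    flip = rng.random() < policy.hflip_prob
    scale = rng.uniform(*policy.scale_range)
    angle = np.deg2rad(rng.uniform(-policy.rotate_deg, policy.rotate_deg))
    tx = rng.uniform(-policy.translate_frac, policy.translate_frac) * w
    ty = rng.uniform(-policy.translate_frac, policy.translate_frac) * h

    # similarity about the image centre, then optional flip
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cosa, sina = np.cos(angle), np.sin(angle)
    mat = np.array(
        [
            [scale * cosa, -scale * sina, cx + tx - scale * (cosa * cx - sina * cy)],
            [scale * sina, scale * cosa, cy + ty - scale * (sina * cx + cosa * cy)],
            [0, 0, 1],
        ]
    )
    if flip:
        fmat = np.array([[-1.0, 0.0, w - 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        mat = fmat @ mat

    img = np.asarray(image, dtype=np.float64)
    warped = warp(
        img, AffineTransform(matrix=np.linalg.inv(mat)),  # warp wants the output->input map
        output_shape=img.shape[:2], order=1, mode="edge", preserve_range=True,
    )
    if policy.gauss_noise_sd > 0:
        warped = warped + rng.normal(0.0, policy.gauss_noise_sd, size=warped.shape)
    out_img = np.clip(warped, 0, 255).astype(np.uint8)

    arr = ann.keypoints.as_array()
    new_xy = _apply_points(mat, arr[:, :2])
    vis = arr[:, 2].copy()
    inside = (new_xy[:, 0] >= 0) & (new_xy[:, 0] < w) & (new_xy[:, 1] >= 0) & (new_xy[:, 1] < h)
    vis[~inside] = VIS_NOT_LABELED
    kps = KeypointSet.from_array(np.column_stack([new_xy, vis]))

    x1, y1, x2, y2 = ann.box
    corners = _apply_points(mat, np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]))
    bx1, by1 = corners.min(axis=0)
    bx2, by2 = corners.max(axis=0)
    box = (max(bx1, 0.0), max(by1, 0.0), min(bx2, float(w)), min(by2, float(h)))

    contour = _apply_points(mat, ann.contour) if ann.contour is not None else None
    new_ann = AnnotatedImage(
        image_path=ann.image_path,
        image_size=ann.image_size,
        keypoints=kps,
        box=box,
        ruler_endpoints=_apply_points(mat, ann.ruler_endpoints),
        ruler_length_m=ann.ruler_length_m,
        individual_id=ann.individual_id,
        view_index=ann.view_index,
        contour=contour,
    )
    return out_img, new_ann


# ---------------------------------------------------------------------------
# splitting and training-set expansion
# ---------------------------------------------------------------------------


def split_by_individual(ids, ratios=(7, 2, 1), seed: int = 0) -> dict[str, list]:
    """Partition unique individual IDs into train/val/test.

    Sizes are floor proportions of the shuffled unique-ID list with the
    remainder assigned to train, so no image of one individual can appear in
    two subsets."""
    unique = sorted(set(ids))
    if len(unique) < 3:
        raise SplitError(f"need at least 3 unique individuals, got {len(unique)}")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise SplitError("ratios must be positive")
    fracs = ratios / ratios.sum()
    rng = np.random.default_rng(seed)
    order = list(np.array(unique)[rng.permutation(len(unique))])
    n = len(order)
    n_val = int(np.floor(n * fracs[1]))
    n_test = int(np.floor(n * fracs[2]))
    n_train = n - n_val - n_test
    return {
        "train": sorted(order[:n_train]),
        "val": sorted(order[n_train : n_train + n_val]),
        "test": sorted(order[n_train + n_val :]),
    }


def expand_training_set(
    manifest: pd.DataFrame,
    policy: AugmentPolicy,
    out_dir,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``multiplicity`` augmented copies per training image.

    Originals are always retained; augmented files carry ``_aug<k>``
    provenance suffixes and re-validate under :func:`read_labelme`."""
    import imageio.v3 as iio

    policy.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rows = [dict(r) | {"augmented": 0} for _, r in manifest.iterrows()]
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(len(manifest) * max(policy.multiplicity, 1) + 1)
    i = 0
    for _, row in manifest.iterrows():
        ann = read_labelme(row["annotation"])
        img = iio.imread(row["image"])
        stem = Path(row["image"]).stem
        for k in range(policy.multiplicity):
            aug_img, aug_ann = augment(ann, img, policy, rng_seed=int(seeds[i] % 2**31))
            i += 1
            img_path = out_dir / "images" / f"{stem}_aug{k}.png"
            ann_path = out_dir / "annotations" / f"{stem}_aug{k}.json"
            aug_ann.image_path = str(img_path)
            iio.imwrite(img_path, aug_img)
            write_labelme(aug_ann, ann_path)
            rows.append(
                {
                    "individual_id": row["individual_id"],
                    "view": row["view"],
                    "image": str(img_path),
                    "annotation": str(ann_path),
                    "augmented": 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# letterbox resize (aspect-preserving, grey padding)
# ---------------------------------------------------------------------------


@dataclass
class Letterbox:
    """Aspect-preserving resize to a square side with grey padding.

    ``to_input`` maps original pixel coordinates into the padded frame;
    ``to_original`` is its exact inverse.
    """

    src_size: tuple[int, int]  # (H, W)
    dst: int
    pad_value: float = 114.0

    def __post_init__(self):
        h, w = self.src_size
        self.scale = self.dst / max(h, w)
        new_h, new_w = int(round(h * self.scale)), int(round(w * self.scale))
        self.new_size = (new_h, new_w)
        self.pad_top = (self.dst - new_h) // 2
        self.pad_left = (self.dst - new_w) // 2

    def apply(self, image: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        img = np.asarray(image, dtype=np.float64)
        resized = resize(img, self.new_size, order=1, preserve_range=True, anti_aliasing=True)
        out_shape = (self.dst, self.dst) + img.shape[2:]
        out = np.full(out_shape, self.pad_value, dtype=np.float64)
        out[self.pad_top : self.pad_top + self.new_size[0], self.pad_left : self.pad_left + self.new_size[1]] = resized
        return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out

    def to_input(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = pts * self.scale
        out[..., 0] += self.pad_left
        out[..., 1] += self.pad_top
        return out

    def to_original(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).copy()
        pts[..., 0] -= self.pad_left
        pts[..., 1] -= self.pad_top
        return pts / self.scale
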