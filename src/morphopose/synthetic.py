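"""Synthetic side-view quadruped scenes with allometric ground truth.

The generator stands in for a field-collected livestock dataset: each
*individual* is a latent body geometry (overall scale, trunk aspect, chest
depth, cannon width, girth eccentricity); each *view* is a rendered
silhouette image with natural pose jitter, a ground-plane reference ruler of
known physical length (1.1 m), Labelme-style keypoint annotations, and one
shared row of per-individual body measurements.

Geometry is a 2-D articulated template — a superellipse trunk, four
rectangular legs, a neck/head wedge and a tail — chosen so the ten canonical
keypoints are well defined on the silhouette boundary and the five
measurements are allometrically coupled:

* the three linear measures (body length, body height, oblique body length)
  are exactly 100x the corresponding keypoint distances in metres;
* chest girth is the perimeter of an ellipse whose semi-major axis is half
  the visible chest depth and whose minor/major ratio is the individual's
  ``girth_eccentricity`` (computed with the complete elliptic integral);
* cannon circumference is ``pi`` times the visible cannon width.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ellipe
from skimage import measure as _skmeasure
from skimage.draw import disk as _disk
from skimage.draw import polygon as _polygon

from .core import (
    KEYPOINT_NAMES,
    MEASUREMENT_FIELDS,
    NAMED_PAIRS,
    AnnotatedImage,
    KeypointSet,
    MeasurementRecord,
)

RULER_LENGTH_M = 1.1


class ConfigurationError(ValueError):
    pass


class FramingError(ValueError):
    pass


@dataclass
class PopulationConfig:
    """Distribution parameters of the synthetic population.

    ``size_scale`` (standing height, metres) and ``trunk_aspect`` are
    truncated normals.  The shape fractions follow the allometry of real
    livestock: bone and girth dimensions scale almost isometrically with
    body size, with only a few percent of individual residual variation
    (condition, breed), so each fraction is its mean times a log-normal
    residual of coefficient of variation ``*_cv``.  This coupling is what
    makes the five measurements jointly predictable from side-view
    geometry, as in real conformation data.
    """

    size_scale_mean: float = 1.20
    size_scale_sd: float = 0.12
    size_scale_bounds: tuple[float, float] = (0.80, 1.60)
    trunk_aspect_mean: float = 1.25
    trunk_aspect_sd: float = 0.05
    trunk_aspect_bounds: tuple[float, float] = (1.05, 1.45)
    chest_depth_frac_mean: float = 0.52
    chest_depth_frac_cv: float = 0.025
    chest_depth_frac_bounds: tuple[float, float] = (0.40, 0.64)
    cannon_width_frac_mean: float = 0.060
    cannon_width_frac_cv: float = 0.030
    cannon_width_frac_bounds: tuple[float, float] = (0.040, 0.085)
    girth_eccentricity_mean: float = 0.82
    girth_eccentricity_cv: float = 0.030
    girth_eccentricity_bounds: tuple[float, float] = (0.60, 0.98)

    def validate(self) -> "PopulationConfig":
        for name in ("size_scale", "trunk_aspect"):
            if getattr(self, f"{name}_sd") <= 0:
                raise ConfigurationError(f"{name}_sd must be > 0")
        for name in ("chest_depth_frac", "cannon_width_frac", "girth_eccentricity"):
            if getattr(self, f"{name}_cv") <= 0:
                raise ConfigurationError(f"{name}_cv must be > 0")
        for name in ("size_scale", "trunk_aspect", "chest_depth_frac", "cannon_width_frac", "girth_eccentricity"):
            lo, hi = getattr(self, f"{name}_bounds")
            if not (0 < lo < hi):
                raise ConfigurationError(f"{name}_bounds must satisfy 0 < lo < hi, got {(lo, hi)}")
        return self


@dataclass
class IndividualLatent:
    individual_id: str
    size_scale: float
    trunk_aspect: float
    chest_depth_frac: float
    cannon_width_frac: float
    girth_eccentricity: float
    pose_seed: int

    def validate(self) -> "IndividualLatent":
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")
        for name in ("chest_depth_frac", "cannon_width_frac", "girth_eccentricity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        return self


def _trunc_normal(rng, mean, sd, bounds, max_tries=200):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    return float(np.clip(mean, *bounds))


def sample_individual(rng_seed: int, population_config: PopulationConfig | None = None, individual_id: str | None = None) -> IndividualLatent:
    """Draw one individual's latent geometry; deterministic under the seed."""
    cfg = (population_config or PopulationConfig()).validate()
    rng = np.random.default_rng(rng_seed)

    def frac(name):
        v = getattr(cfg, f"{name}_mean") * float(np.exp(rng.normal(0.0, getattr(cfg, f"{name}_cv"))))
        return float(np.clip(v, *getattr(cfg, f"{name}_bounds")))

    latent = IndividualLatent(
        individual_id=individual_id if individual_id is not None else f"ind{rng_seed:04d}",
        size_scale=_trunc_normal(rng, cfg.size_scale_mean, cfg.size_scale_sd, cfg.size_scale_bounds),
        trunk_aspect=_trunc_normal(rng, cfg.trunk_aspect_mean, cfg.trunk_aspect_sd, cfg.trunk_aspect_bounds),
        chest_depth_frac=frac("chest_depth_frac"),
        cannon_width_frac=frac("cannon_width_frac"),
        girth_eccentricity=frac("girth_eccentricity"),
        pose_seed=int(rng.integers(0, 2**31 - 1)),
    )
    return latent.validate()


# ---------------------------------------------------------------------------
# template geometry (metric, metres, ground plane y = 0, y up, faces left)
# ---------------------------------------------------------------------------

_SUPER_N = 4.0  # superellipse exponent of the trunk


def _trunk_params(latent: IndividualLatent):
    h = latent.size_scale
    length = h * latent.trunk_aspect
    depth = h * latent.chest_depth_frac
    cx, cy = length / 2.0, h - depth / 2.0
    return h, length, depth, cx, cy


def _trunk_boundary_x(rel_y: float) -> float:
    """Half-width fraction of the trunk at relative height ``rel_y`` in [-1, 1]."""
    return (1.0 - abs(rel_y) ** _SUPER_N) ** (1.0 / _SUPER_N)


def _trunk_boundary_y(rel_x: float) -> float:
    return (1.0 - abs(rel_x) ** _SUPER_N) ** (1.0 / _SUPER_N)


_FRONT_LEG_X = 0.18  # fraction of trunk length
_HIND_LEG_X = 0.82
_CANNON_Y = 0.18  # fraction of height


def keypoints_from_latent(latent: IndividualLatent, pose_jitter: float = 0.0) -> KeypointSet:
    """Canonical metric keypoints; ``pose_jitter`` is the SD of positional
    jitter as a fraction of body height (drawn from ``latent.pose_seed``)."""
    latent.validate()
    if pose_jitter < 0:
        raise ValueError("pose_jitter must be >= 0")
    h, length, depth, cx, cy = _trunk_params(latent)
    half_l, half_d = length / 2.0, depth / 2.0
    x_leg = _FRONT_LEG_X * length
    w_can = latent.cannon_width_frac * h

    rel_leg = abs(x_leg - cx) / half_l
    top_y = cy + half_d * _trunk_boundary_y(rel_leg)
    rel_chest = abs(0.35 * length - cx) / half_l
    chest_top = cy + half_d * _trunk_boundary_y(rel_chest)
    chest_bot = cy - half_d * _trunk_boundary_y(rel_chest)
    obl = 0.5  # relative trunk height of the oblique anchor points
    x_obl = half_l * _trunk_boundary_x(obl)

    pts = {
        "body_length_anterior": (cx - half_l, cy),
        "body_length_posterior": (cx + half_l, cy),
        "body_height_top": (x_leg, top_y),
        "body_height_ground": (x_leg, 0.0),
        "chest_girth_upper": (0.35 * length, chest_top),
        "chest_girth_lower": (0.35 * length, chest_bot),
        "oblique_length_anterior": (cx - x_obl, cy + obl * half_d),
        "oblique_length_posterior": (cx + x_obl, cy - obl * half_d),
        "cannon_outer": (x_leg - w_can / 2.0, _CANNON_Y * h),
        "cannon_inner": (x_leg + w_can / 2.0, _CANNON_Y * h),
    }
    if pose_jitter > 0:
        rng = np.random.default_rng(latent.pose_seed)
        sd = pose_jitter * h
        for name in KEYPOINT_NAMES:
            x, y = pts[name]
            dx, dy = rng.normal(0.0, sd, size=2)
            if name == "body_height_ground":
                dy = 0.0  # the ground contact stays on the ground plane
            pts[name] = (x + dx, max(y + dy, 0.0))
    return KeypointSet({n: (x, y, 2) for n, (x, y) in pts.items()})


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact perimeter of an ellipse with semi-axes a >= b > 0."""
    if a < b:
        a, b = b, a
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def measurements_from_latent(
    latent: IndividualLatent,
    kps: KeypointSet,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    relative: bool = False,
    max_tries: int = 100,
) -> MeasurementRecord:
    """Ground-truth measurements (cm) from a keypoint configuration.

    ``noise_sd`` is an additive SD in cm, or a fractional SD when
    ``relative`` (emulating repeat-and-average manual measurement error).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dists = {name: kps.distance(a, b) for name, (a, b) in NAMED_PAIRS.items()}
    depth = dists["chest_girth"]  # visible chest depth, metres
    a = depth / 2.0
    b = latent.girth_eccentricity * a
    clean = np.array(
        [
            dists["body_length"] * 100.0,
            dists["body_height"] * 100.0,
            dists["oblique_body_length"] * 100.0,
            ellipse_perimeter(a, b) * 100.0,
            np.pi * dists["cannon_circumference"] * 100.0,
        ]
    )
    if noise_sd == 0.0:
        return MeasurementRecord.from_array(clean, individual_id=latent.individual_id).validate()
    rng = rng or np.random.default_rng(latent.pose_seed)
    sd = clean * noise_sd if relative else np.full(5, noise_sd)
    for _ in range(max_tries):
        noisy = clean + rng.normal(0.0, sd)
        try:
            return MeasurementRecord.from_array(noisy, individual_id=latent.individual_id).validate()
        except ValueError:
            continue
    raise ValueError("could not draw a valid noisy measurement record")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Camera/scene description for one rendered view."""

    image_size: tuple[int, int] = (320, 320)  # (H, W)
    pixels_per_meter: float = 150.0
    origin_px: tuple[float, float] = (60.0, 300.0)  # pixel of metric (0, 0): (x, ground row)
    ruler_start_m: float = 0.0  # metric x of the left ruler end (on the ground)
    ruler_length_m: float = RULER_LENGTH_M
    background_level: float = 0.70
    illumination_gain: float = 1.0
    mirror: bool = False

    def __post_init__(self):
        if self.pixels_per_meter <= 0:
            raise ConfigurationError("pixels_per_meter must be positive")
        if not 0.0 <= self.background_level <= 1.0:
            raise ConfigurationError("background_level must lie in [0, 1]")

    @property
    def ruler_endpoints(self) -> np.ndarray:
        p0 = self.to_pixels(np.array([[self.ruler_start_m, 0.0]]))[0]
        p1 = self.to_pixels(np.array([[self.ruler_start_m + self.ruler_length_m, 0.0]]))[0]
        return np.array([p0, p1])

    def to_pixels(self, xy_m: np.ndarray) -> np.ndarray:
        """Metric (x right, y up, ground y=0) -> pixel (x right, y down)."""
        xy_m = np.asarray(xy_m, dtype=float)
        ox, gy = self.origin_px
        out = np.empty_like(xy_m)
        out[..., 0] = ox + self.pixels_per_meter * xy_m[..., 0]
        out[..., 1] = gy - self.pixels_per_meter * xy_m[..., 1]
        if self.mirror:
            out[..., 0] = self.image_size[1] - 1 - out[..., 0]
        return out

    def to_meters(self, xy_px: np.ndarray) -> np.ndarray:
        xy_px = np.asarray(xy_px, dtype=float)
        ox, gy = self.origin_px
        x = xy_px[..., 0].copy()
        if self.mirror:
            x = self.image_size[1] - 1 - x
        out = np.empty_like(xy_px)
        out[..., 0] = (x - ox) / self.pixels_per_meter
        out[..., 1] = (gy - xy_px[..., 1]) / self.pixels_per_meter
        return out


def _poly_px(scene: SceneSpec, pts_m) -> np.ndarray:
    return scene.to_pixels(np.asarray(pts_m, dtype=float))


def _fill(mask_img, shade_img, poly_px, shade):
    rr, cc = _polygon(poly_px[:, 1], poly_px[:, 0], shape=mask_img.shape)
    mask_img[rr, cc] = True
    shade_img[rr, cc] = shade


def _leg_polys(x_center, width, h, depth, stance_dx=0.0):
    """Rectangular leg segments: upper, cannon, hoof (metric polygons)."""
    top = h - depth * 0.85
    segs = []
    for y0, y1, w in (
        (top, 0.45 * h, 1.7 * width),
        (0.45 * h, 0.05 * h, width),
        (0.05 * h, 0.0, 1.35 * width),
    ):
        x0 = x_center - w / 2.0
        x1 = x_center + w / 2.0
        x0b, x1b = x0 + stance_dx, x1 + stance_dx
        segs.append([(x0, y0), (x1, y0), (x1b, y1), (x0b, y1)])
    return segs


def _superellipse_poly(cx, cy, half_l, half_d, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = cx + half_l * np.sign(ct) * np.abs(ct) ** (2.0 / _SUPER_N)
    y = cy + half_d * np.sign(st) * np.abs(st) ** (2.0 / _SUPER_N)
    return np.column_stack([x, y])


def render_scene(
    latent: IndividualLatent,
    kps: KeypointSet,
    scene: SceneSpec,
    rng_seed: int = 0,
    image_path: str = "",
    view_index: int = 0,
) -> tuple[np.ndarray, AnnotatedImage]:
    """Rasterise the silhouette + ruler; return (RGB image, annotation).

    The annotation's pixel keypoints are exactly the metric keypoints mapped
    through ``scene.to_pixels``; a keypoint outside the frame raises
    :class:`FramingError` naming it.
    """
    h_img, w_img = scene.image_size
    rng = np.random.default_rng(rng_seed)
    h, length, depth, cx, cy = _trunk_params(latent)

    kp_px = scene.to_pixels(kps.as_array(with_visibility=False))
    for name, (x, y) in zip(KEYPOINT_NAMES, kp_px):
        if not (0 <= x < w_img and 0 <= y < h_img):
            raise FramingError(f"keypoint {name!r} maps outside the frame: ({x:.1f}, {y:.1f})")

    mask = np.zeros((h_img, w_img), dtype=bool)
    shade = np.zeros((h_img, w_img), dtype=float)
    w_can = latent.cannon_width_frac * h

    # far-side legs (offset, darker), then trunk, near legs, neck/head, tail
    for x_c, wid in ((_FRONT_LEG_X * length, w_can), (_HIND_LEG_X * length, 1.15 * w_can)):
        for seg in _leg_polys(x_c + 0.05 * length, wid, h, depth, stance_dx=0.02 * length):
            _fill(mask, shade, _poly_px(scene, seg), 0.55)
    _fill(mask, shade, _poly_px(scene, _superellipse_poly(cx, cy, length / 2, depth / 2)), 1.0)
    for x_c, wid in ((_FRONT_LEG_X * length, w_can), (_HIND_LEG_X * length, 1.15 * w_can)):
        for seg in _leg_polys(x_c, wid, h, depth, stance_dx=-0.01 * length):
            _fill(mask, shade, _poly_px(scene, seg), 0.95)
    # a prominent head/neck: the orientation cue any side view of a real
    # animal carries.  The neck attaches above the mid-trunk line and the
    # tail hangs from the upper rump, so the silhouette edges that define
    # the body-length endpoints (front/rear boundary at mid-trunk height)
    # stay exposed and unambiguous.
    neck = [
        (0.10 * length, h),
        (-0.14 * length, 1.00 * h),
        (-0.26 * length, 0.82 * h),
        (0.00 * length, 0.80 * h),
    ]
    _fill(mask, shade, _poly_px(scene, neck), 0.9)
    head_c = scene.to_pixels(np.array([[-0.22 * length, 0.86 * h]]))[0]
    rr, cc = _disk((head_c[1], head_c[0]), 0.12 * length * scene.pixels_per_meter, shape=mask.shape)
    mask[rr, cc] = True
    shade[rr, cc] = 0.9
    muzzle = [(-0.24 * length, 0.84 * h), (-0.37 * length, 0.74 * h), (-0.32 * length, 0.66 * h), (-0.20 * length, 0.74 * h)]
    _fill(mask, shade, _poly_px(scene, muzzle), 0.85)
    tail = [(0.99 * length, cy + 0.45 * depth), (1.07 * length, cy + 0.28 * depth), (1.03 * length, cy + 0.12 * depth)]
    _fill(mask, shade, _poly_px(scene, tail), 0.8)

    # background: gradient + patch noise; body: dark coat with fur texture
    yy = np.linspace(0, 1, h_img)[:, None]
    bg = scene.background_level * (0.85 + 0.3 * yy) + 0.04 * rng.standard_normal((h_img, w_img))
    coat = 0.16 + 0.10 * shade + 0.05 * rng.standard_normal((h_img, w_img))
    img = np.where(mask, coat, bg)

    # ruler: alternating high/low contrast bar on the ground line
    ends = scene.ruler_endpoints
    (x0r, y0r), (x1r, y1r) = ends
    n_seg = 11
    for i in range(n_seg):
        xa = x0r + (x1r - x0r) * i / n_seg
        xb = x0r + (x1r - x0r) * (i + 1) / n_seg
        lo, hi = sorted((xa, xb))
        c0, c1 = int(np.floor(lo)), int(np.ceil(hi))
        r0, r1 = int(round(y0r)) - 3, int(round(y0r)) + 3
        c0, c1 = max(c0, 0), min(c1, w_img)
        r0, r1 = max(r0, 0), min(r1, h_img)
        img[r0:r1, c0:c1] = 0.05 if i % 2 else 0.95

    img = np.clip(img * scene.illumination_gain, 0.0, 1.0)
    rgb = (np.stack([img * 1.02, img, img * 0.94], axis=-1).clip(0, 1) * 255).astype(np.uint8)

    rows, cols = np.nonzero(mask)
    box = (float(cols.min()), float(rows.min()), float(cols.max() + 1), float(rows.max() + 1))
    contours = _skmeasure.find_contours(mask.astype(float), 0.5)
    contour = None
    if contours:
        big = max(contours, key=len)[::10]
        contour = np.column_stack([big[:, 1], big[:, 0]])  # (x, y) px

    ann = AnnotatedImage(
        image_path=image_path,
        image_size=(h_img, w_img),
        keypoints=KeypointSet.from_array(np.column_stack([kp_px, np.full(len(kp_px), 2)])),
        box=box,
        ruler_endpoints=ends,
        ruler_length_m=scene.ruler_length_m,
        individual_id=latent.individual_id,
        view_index=view_index,
        contour=contour,
    )
    return rgb, ann


def _fit_scene(latent: IndividualLatent, rng: np.random.Generator, image_size, base_ppm, mirror_prob) -> SceneSpec:
    """Choose a scene that frames the animal with margins, ruler on the ground."""
    h_img, w_img = image_size
    h, length, depth, cx, cy = _trunk_params(latent)
    span_left, span_right = 0.40 * length, 1.09 * length
    margin = 14.0
    ppm_x = (w_img - 2 * margin) / (span_left + span_right)
    ground_y = h_img - 16.0 - rng.uniform(0, 6)
    ppm_y = (ground_y - margin) / (1.06 * h)  # headroom for the raised head
    ppm = min(base_ppm * rng.uniform(0.96, 1.04), ppm_x, ppm_y)
    lo = margin + span_left * ppm
    hi = w_img - margin - span_right * ppm
    ox = rng.uniform(lo, hi) if hi > lo else (lo + hi) / 2
    ruler_px = RULER_LENGTH_M * ppm
    rx_px = rng.uniform(6, max(7.0, w_img - 6 - ruler_px))
    return SceneSpec(
        image_size=tuple(image_size),
        pixels_per_meter=float(ppm),
        origin_px=(float(ox), float(ground_y)),
        ruler_start_m=float((rx_px - ox) / ppm),
        background_level=float(rng.uniform(0.58, 0.80)),
        illumination_gain=float(rng.uniform(0.88, 1.12)),
        mirror=bool(rng.random() < mirror_prob),
    )


def generate_dataset(
    n_individuals: int,
    views_per_individual: int,
    out_dir,
    seed: int = 0,
    population_config: PopulationConfig | None = None,
    measurement_noise_frac: float = 0.01,
    pose_jitter: float = 0.02,
    image_size: tuple[int, int] = (320, 320),
    base_ppm: float = 150.0,
    mirror_prob: float = 0.5,
) -> pd.DataFrame:
    """Write a full synthetic dataset and return its manifest.

    Output layout: ``images/<id>_v<k>.png``, ``annotations/<id>_v<k>.json``,
    ``measurements.csv`` (one row per individual), ``manifest.csv``.
    """
    from .annotations import write_labelme  # deferred: annotations also reads our output
    import imageio.v3 as iio

    if n_individuals < 1 or views_per_individual < 1:
        raise ConfigurationError("need at least one individual and one view")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(seed)
    meas_rows, manifest_rows = [], []
    for i, child in enumerate(root.spawn(n_individuals)):
        child_seeds = child.generate_state(3 + views_per_individual)
        ind_id = f"ind{i:04d}"
        latent = sample_individual(int(child_seeds[0] % 2**31), population_config, individual_id=ind_id)
        canonical = keypoints_from_latent(latent, pose_jitter=0.0)
        record = measurements_from_latent(
            latent,
            canonical,
            noise_sd=measurement_noise_frac,
            rng=np.random.default_rng(int(child_seeds[1] % 2**31)),
            relative=True,
        ) if measurement_noise_frac > 0 else measurements_from_latent(latent, canonical)
        meas_rows.append({"individual_id": ind_id, **{f: getattr(record, f) for f in MEASUREMENT_FIELDS}, "body_weight": ""})

        for v in range(views_per_individual):
            vseed = int(child_seeds[3 + v] % 2**31)
            vrng = np.random.default_rng(vseed)
            view_latent = IndividualLatent(**{**vars(latent), "pose_seed": vseed})
            kps = keypoints_from_latent(view_latent, pose_jitter=pose_jitter)
            scene = _fit_scene(latent, vrng, image_size, base_ppm, mirror_prob)
            stem = f"{ind_id}_v{v}"
            img_path = out_dir / "images" / f"{stem}.png"
            ann_path = out_dir / "annotations" / f"{stem}.json"
            img, ann = render_scene(view_latent, kps, scene, rng_seed=vseed, image_path=str(img_path), view_index=v)
            iio.imwrite(img_path, img)
            write_labelme(ann, ann_path)
            manifest_rows.append(
                {"individual_id": ind_id, "view": v, "image": str(img_path), "annotation": str(ann_path)}
            )

    pd.DataFrame(meas_rows).to_csv(out_dir / "measurements.csv", index=False)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def simulate_feature_study(
    n_individuals: int,
    views_per_individual: int = 3,
    seed: int = 0,
    pose_jitter: float = 0.02,
    measurement_noise_frac: float = 0.01,
    mode: str = "named5",
    population_config: PopulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression-stage study without rendering: per-view distance features
    straight from the metric keypoints (equivalent to perfectly annotated
    images) plus the per-individual measurement table.

    Returns ``(features, measurements)``; features carry ``individual_id``
    and one column per keypoint pair.
    """
    from .morphometry import ALL_PAIRS, pair_names

    pairs = list(NAMED_PAIRS.values()) if mode == "named5" else list(ALL_PAIRS)
    cols = pair_names(mode)
    root = np.random.SeedSequence(seed)
    feat_rows, meas_rows = [], []
    for i, child in enumerate(root.spawn(n_individuals)):
        seeds = child.generate_state(2 + views_per_individual)
        ind_id = f"ind{i:04d}"
        latent = sample_individual(int(seeds[0] % 2**31), population_config, individual_id=ind_id)
        canonical = keypoints_from_latent(latent, 0.0)
        record = measurements_from_latent(
            latent, canonical, noise_sd=measurement_noise_frac,
            rng=np.random.default_rng(int(seeds[1] % 2**31)), relative=True,
        ) if measurement_noise_frac > 0 else measurements_from_latent(latent, canonical)
        meas_rows.append({"individual_id": ind_id, **{f: getattr(record, f) for f in MEASUREMENT_FIELDS}})
        for v in range(views_per_individual):
            vlat = IndividualLatent(**{**vars(latent), "pose_seed": int(seeds[2 + v] % 2**31)})
            kps = keypoints_from_latent(vlat, pose_jitter)
            feats = [100.0 * kps.distance(a, b) for a, b in pairs]
            feat_rows.append({"individual_id": ind_id, **dict(zip(cols, feats))})
    return pd.DataFrame(feat_rows), pd.DataFrame(meas_rows).set_index("individual_id")
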