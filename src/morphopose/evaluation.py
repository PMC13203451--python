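"""Evaluation: regression error metrics, OKS-based detection metrics,
perturbation robustness, split stability and the ablation harness.

Pose quality uses COCO-style object keypoint similarity (OKS),

    OKS = mean over visible keypoints of exp(-d_i^2 / (2 s^2 k^2)),

with ``s^2`` the ground-truth box area and a uniform per-keypoint tolerance
constant ``k`` (no published sigmas exist for livestock landmarks); mAP
averages AP over OKS thresholds 0.50:0.05:0.95.  PCK (fraction of keypoints
within a tolerance times the box diagonal) is reported alongside as a
sigma-free check.

Regression metrics are computed per target, then macro-averaged across the
five measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .core import MEASUREMENT_FIELDS, MeasurementRecord

OKS_THRESHOLDS = np.arange(0.50, 0.96, 0.05)
DEFAULT_OKS_K = 0.05


class PairingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------


@dataclass
class RegressionMetrics:
    rmse: float
    mae: float
    mape_percent: float
    r2: float
    per_target: pd.DataFrame

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "mape_percent": self.mape_percent, "r2": self.r2}


def _records_to_array(records) -> np.ndarray:
    if isinstance(records, np.ndarray):
        return np.asarray(records, dtype=float)
    return np.stack([r.as_array() if isinstance(r, MeasurementRecord) else np.asarray(r, float) for r in records])


def regression_metrics(pred, truth) -> RegressionMetrics:
    """RMSE / MAE / MAPE(%) / R^2, per target and macro-averaged."""
    p, t = _records_to_array(pred), _records_to_array(truth)
    if p.shape != t.shape or len(p) == 0:
        raise PairingError(f"prediction/truth shapes differ or empty: {p.shape} vs {t.shape}")
    if np.any(t == 0):
        raise ValueError("MAPE undefined: ground truth contains zeros")
    rows = []
    for j, name in enumerate(MEASUREMENT_FIELDS[: p.shape[1]]):
        pj, tj = p[:, j], t[:, j]
        if np.allclose(tj.std(), 0.0):
            raise ValueError(f"zero-variance ground truth for target {name!r}: R^2 undefined")
        rows.append(
            {
                "target": name,
                "rmse": float(np.sqrt(mean_squared_error(tj, pj))),
                "mae": float(mean_absolute_error(tj, pj)),
                "mape_percent": float(100.0 * np.mean(np.abs(pj - tj) / np.abs(tj))),
                "r2": float(r2_score(tj, pj)),
            }
        )
    per_target = pd.DataFrame(rows).set_index("target")
    return RegressionMetrics(
        rmse=float(per_target["rmse"].mean()),
        mae=float(per_target["mae"].mean()),
        mape_percent=float(per_target["mape_percent"].mean()),
        r2=float(per_target["r2"].mean()),
        per_target=per_target,
    )


# ---------------------------------------------------------------------------
# OKS / detection metrics
# ---------------------------------------------------------------------------


def oks(det_kps: np.ndarray, gt_kps: np.ndarray, gt_box, k: float = DEFAULT_OKS_K) -> float:
    """Object keypoint similarity between a detection and a ground truth.

    ``det_kps``: (K, 2+) predicted coordinates; ``gt_kps``: (K, 3) with
    visibility in the third column; ``gt_box``: (x1, y1, x2, y2).
    """
    det = np.asarray(det_kps, dtype=float)[:, :2]
    gt = np.asarray(gt_kps, dtype=float)
    if gt.shape[1] < 3:
        gt = np.column_stack([gt, np.full(len(gt), 2.0)])
    vis = gt[:, 2] > 0
    if not vis.any():
        raise ValueError("OKS undefined without visible ground-truth keypoints")
    x1, y1, x2, y2 = gt_box
    s2 = max((x2 - x1) * (y2 - y1), 1e-9)
    d2 = np.sum((det[vis] - gt[vis, :2]) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * s2 * k**2))))


def pck(det_kps, gt_kps, gt_box, frac: float = 0.1) -> float:
    """Fraction of visible keypoints within ``frac`` x box diagonal."""
    det = np.asarray(det_kps, dtype=float)[:, :2]
    gt = np.asarray(gt_kps, dtype=float)
    vis = gt[:, 2] > 0 if gt.shape[1] > 2 else np.ones(len(gt), bool)
    x1, y1, x2, y2 = gt_box
    diag = float(np.hypot(x2 - x1, y2 - y1))
    d = np.linalg.norm(det[vis] - gt[vis, :2], axis=1)
    return float(np.mean(d <= frac * diag))


@dataclass
class DetectionMetrics:
    map_oks: float  # mAP over OKS in 0.50:0.05:0.95
    ap50: float
    precision: float  # at OKS 0.50 and the operating confidence threshold
    recall: float
    mean_pck: float
    per_keypoint_pck: np.ndarray


def _average_precision(scores, matched, n_gt) -> float:
    """All-point interpolated AP from score-ranked match flags."""
    if n_gt == 0:
        return float("nan")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores))
    tp = np.asarray(matched, dtype=float)[order]
    fp = 1.0 - tp
    tp_cum, fp_cum = np.cumsum(tp), np.cumsum(fp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # envelope + integrate over recall steps
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def detection_metrics(detections, ground_truths, k: float = DEFAULT_OKS_K, conf_threshold: float = 0.25,
                      pck_frac: float = 0.1) -> DetectionMetrics:
    """Score detections against ground truths over a set of images.

    ``detections``: per image, a list of dicts with ``score`` and ``kps``
    ((K, 2+) array); ``ground_truths``: per image, a list of dicts with
    ``kps`` ((K, 3)) and ``box``.  Matching is greedy by OKS per threshold.
    """
    if len(detections) != len(ground_truths):
        raise PairingError("detections and ground truths must align per image")
    n_gt = sum(len(g) for g in ground_truths)
    aps = []
    match50 = None
    for thr in OKS_THRESHOLDS:
        scores, matched = [], []
        for dets, gts in zip(detections, ground_truths):
            taken = np.zeros(len(gts), dtype=bool)
            for det in sorted(dets, key=lambda d: -d["score"]):
                sims = [
                    -1.0 if taken[j] else oks(det["kps"], g["kps"], g["box"], k) for j, g in enumerate(gts)
                ]
                best = int(np.argmax(sims)) if sims else -1
                ok = best >= 0 and sims[best] >= thr
                if ok:
                    taken[best] = True
                scores.append(det["score"])
                matched.append(ok)
        aps.append(_average_precision(scores, matched, n_gt))
        if np.isclose(thr, 0.5):
            match50 = (np.asarray(scores), np.asarray(matched, dtype=bool))
    scores50, matched50 = match50
    keep = scores50 >= conf_threshold
    n_det = int(keep.sum())
    tp = int(matched50[keep].sum())
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_gt if n_gt else float("nan")

    pcks = []
    kp_hits = []
    for dets, gts in zip(detections, ground_truths):
        if not gts:
            continue
        g = gts[0]
        if dets:
            best = max(dets, key=lambda d: d["score"])
            pcks.append(pck(best["kps"], g["kps"], g["box"], pck_frac))
            det = np.asarray(best["kps"], dtype=float)[:, :2]
            gt = np.asarray(g["kps"], dtype=float)
            x1, y1, x2, y2 = g["box"]
            diag = float(np.hypot(x2 - x1, y2 - y1))
            kp_hits.append(np.linalg.norm(det - gt[:, :2], axis=1) <= pck_frac * diag)
        else:
            pcks.append(0.0)
            kp_hits.append(np.zeros(len(g["kps"]), dtype=bool))
    return DetectionMetrics(
        map_oks=float(np.mean(aps)),
        ap50=float(aps[0]),
        precision=float(precision),
        recall=float(recall),
        mean_pck=float(np.mean(pcks)) if pcks else float("nan"),
        per_keypoint_pck=np.mean(np.stack(kp_hits), axis=0) if kp_hits else np.array([]),
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

PERTURBATION_KINDS = ("brightness", "gaussian_noise", "motion_blur", "occlusion")


@dataclass
class PerturbationSpec:
    kind: str
    level: float  # gain for brightness, SD (0-255) for noise, kernel px for blur, area fraction for occlusion

    def validate(self) -> "PerturbationSpec":
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation {self.kind!r}")
        if self.kind == "brightness" and not 0.7 <= self.level <= 1.3:
            raise ValueError("brightness gain limited to +/-30% (0.7..1.3)")
        if self.kind == "occlusion" and not 0.0 <= self.level < 1.0:
            raise ValueError("occlusion fraction must lie in [0, 1)")
        return self


def perturb(image: np.ndarray, spec: PerturbationSpec, seed: int = 0) -> np.ndarray:
    """Photometric perturbation; geometry (hence annotations) unchanged."""
    spec.validate()
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    if spec.kind == "brightness":
        out = img * spec.level
    elif spec.kind == "gaussian_noise":
        out = img + rng.normal(0.0, spec.level, size=img.shape)
    elif spec.kind == "motion_blur":
        length = max(int(spec.level), 1)
        kernel = np.ones((1, length)) / length  # horizontal linear motion
        if img.ndim == 3:
            out = np.stack([convolve(img[..., c], kernel, mode="nearest") for c in range(img.shape[-1])], axis=-1)
        else:
            out = convolve(img, kernel, mode="nearest")
    else:  # occlusion
        h, w = img.shape[:2]
        area = spec.level * h * w
        side = np.sqrt(area)
        ph, pw = int(round(side)), int(round(area / max(side, 1)))
        ph, pw = min(ph, h), min(pw, w)
        y0 = int(rng.integers(0, h - ph + 1))
        x0 = int(rng.integers(0, w - pw + 1))
        out = img.copy()
        fill = np.median(img[:10].reshape(-1, img.shape[-1]), axis=0) if img.ndim == 3 else float(np.median(img[:10]))
        out[y0 : y0 + ph, x0 : x0 + pw] = fill
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(out, 0, 255).astype(image.dtype)
    return out


def default_perturbations() -> list[PerturbationSpec]:
    return [
        PerturbationSpec("brightness", 1.3),
        PerturbationSpec("gaussian_noise", 10.0),
        PerturbationSpec("motion_blur", 9.0),
        PerturbationSpec("occlusion", 0.10),
    ]


def robustness_report(pipeline, test_images, test_truth, specs=None, seed: int = 0) -> pd.DataFrame:
    """One metrics row per condition plus the unperturbed baseline.

    ``pipeline(images) -> (n, 5) predictions``; the same test individuals
    are used throughout.
    """
    specs = default_perturbations() if specs is None else specs
    rows = []
    baseline_pred = pipeline(test_images)
    m = regression_metrics(baseline_pred, test_truth)
    rows.append({"condition": "baseline", "level": 0.0, **m.as_dict()})
    for i, spec in enumerate(specs):
        imgs = [perturb(img, spec, seed=seed + 1000 * i + j) for j, img in enumerate(test_images)]
        m = regression_metrics(pipeline(imgs), test_truth)
        rows.append({"condition": spec.kind, "level": spec.level, **m.as_dict()})
    return pd.DataFrame(rows)


def split_stability(pipeline_builder, ids, seeds, ratios=(7, 2, 1)) -> pd.DataFrame:
    """Re-split by individual, retrain and evaluate once per seed.

    ``pipeline_builder(split_dict, seed) -> RegressionMetrics``; returns one
    row per seed plus ``range``/``sd`` dispersion rows for each metric.
    """
    from .annotations import split_by_individual

    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a stability analysis")
    rows = []
    for seed in seeds:
        split = split_by_individual(ids, ratios=ratios, seed=seed)
        metrics = pipeline_builder(split, seed)
        rows.append({"seed": seed, **metrics.as_dict()})
    df = pd.DataFrame(rows).set_index("seed")
    df.loc["range"] = df.max() - df.min()
    df.loc["sd"] = df.iloc[: len(seeds)].std(ddof=0)
    return df


def ablation_table(presets=("e0", "e1", "e2", "e3", "ep"), scale: str = "nano", input_size: int = 640,
                   evaluate=None, seed: int = 0) -> pd.DataFrame:
    """Complexity (always at the full nano scale) and, optionally,
    detection metrics per ablation preset.

    ``evaluate(preset_name, seed) -> dict`` supplies metric columns when a
    training budget is available; complexity is computed regardless.
    """
    from .posenet import ModelConfig, build_model, complexity

    rows = []
    for name in presets:
        cfg = ModelConfig.preset(name, scale=scale)
        rep = complexity(build_model(cfg, seed=seed), input_size=input_size)
        row = {
            "preset": name.upper(),
            "uib": cfg.use_uib,
            "senetv2": cfg.use_se,
            "ta": cfg.use_ta,
            "params": rep.params,
            "params_mb": rep.params_mb,
            "model_size_mb": rep.model_size_mb,
            "gflops": rep.gflops,
        }
        if evaluate is not None:
            row.update(evaluate(name, seed))
        rows.append(row)
    return pd.DataFrame(rows)
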