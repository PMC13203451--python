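"""Training, decoding and inference for the pose network.

Box decoding follows the anchor-free YOLO convention: each grid cell of
each stride predicts a class logit and four box-side distances as discrete
distributions over ``reg_max`` bins (decoded by softmax expectation); the
animal is assigned to the 3x3 cell neighbourhood of its box centre at
every stride whose bin range can represent the box.

Keypoints use local (heatmap-with-offset) coding: for every keypoint the
head emits a per-cell presence logit plus a short offset from the cell
centre, trained on the cells surrounding that keypoint.  Long-range
regression of body-extreme landmarks from the box centre systematically
shrinks toward the mean extent; local coding keeps each offset within
about one cell and decodes by confidence-weighted averaging around the
presence peak.

The composite loss is a documented design choice: binary cross-entropy on
the class map, complete-IoU on decoded boxes, BCE on the per-keypoint
presence maps and L2 on the local offsets at their positive cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .._engine import SGD, Adam, Tensor, T
from ..annotations import Letterbox, read_labelme
from ..core import KeypointSet
from .architecture import ModelConfig, PoseModel, build_model


@dataclass
class Detection:
    """One decoded animal instance in original-image pixel coordinates."""

    box: tuple[float, float, float, float]
    score: float
    keypoints: KeypointSet  # visibility column carries 2 (trusted) / 1 (low conf)
    keypoint_conf: np.ndarray

    def kps_array(self) -> np.ndarray:
        return self.keypoints.as_array(with_visibility=False)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _to_array(x):
    return x.data if isinstance(x, Tensor) else x


def decode_predictions(raw_outputs, reg_max: int, num_keypoints: int = None, conf_threshold: float = 0.25):
    """Raw multi-scale maps -> candidate boxes (input-frame pixels).

    Returns a list per batch element of dicts with ``box`` (xyxy),
    ``score`` and ``stride``.
    """
    batch = _to_array(raw_outputs[0]["cls"]).shape[0]
    out = [[] for _ in range(batch)]
    for scale in raw_outputs:
        stride = scale["stride"]
        cls = _to_array(scale["cls"])
        box = _to_array(scale["box"])
        n, _, h, w = cls.shape
        conf = _sigmoid(cls[:, 0])
        bins = np.arange(reg_max, dtype=float)
        b = box.reshape(n, 4, reg_max, h, w)
        b = b - b.max(axis=2, keepdims=True)
        e = np.exp(b)
        ltrb = (e / e.sum(axis=2, keepdims=True) * bins[None, None, :, None, None]).sum(axis=2)
        cy, cx = np.mgrid[0:h, 0:w].astype(float) + 0.5
        for bi in range(n):
            ys, xs = np.nonzero(conf[bi] >= conf_threshold)
            for y, x in zip(ys, xs):
                l, t_, r, btm = ltrb[bi, :, y, x]
                out[bi].append(
                    {
                        "box": (
                            (cx[y, x] - l) * stride,
                            (cy[y, x] - t_) * stride,
                            (cx[y, x] + r) * stride,
                            (cy[y, x] + btm) * stride,
                        ),
                        "score": float(conf[bi, y, x]),
                        "stride": stride,
                    }
                )
    return out


# canonical-name indices used by the anatomical decode constraint
_ANTERIOR_KPS = (0, 6)  # body-length / oblique anterior
_POSTERIOR_KPS = (1, 7)  # body-length / oblique posterior
_CANNON_KPS = (8, 9)  # fore-limb cannon pair


def _peak_vote(kk, conf, bi, k, stride, h, w, mask=None):
    c = conf[bi, k]
    if mask is not None:
        c = np.where(mask, c, 0.0)
        if c.max() <= 0:
            c = conf[bi, k]
    py0, px0 = divmod(int(c.argmax()), w)
    iy = np.clip(np.arange(py0 - 1, py0 + 2), 0, h - 1)
    ix = np.clip(np.arange(px0 - 1, px0 + 2), 0, w - 1)
    gy, gx = np.meshgrid(iy, ix, indexing="ij")
    wgt = conf[bi, k, gy, gx].ravel()
    px = ((gx + 0.5 + kk[bi, k, 0, gy, gx]) * stride).ravel()
    py = ((gy + 0.5 + kk[bi, k, 1, gy, gx]) * stride).ravel()
    wsum = wgt.sum() + 1e-12
    return (px * wgt).sum() / wsum, (py * wgt).sum() / wsum, wgt.max()


def decode_keypoints(raw_outputs, num_keypoints: int, box=None):
    """Per-keypoint presence-peak decoding from the finest stride.

    Each keypoint is the confidence-weighted vote of the peak cell and its
    immediate neighbours (cell centre + predicted local offset), keeping
    nearby landmarks from blending.  When a ``box`` (input-frame xyxy) is
    supplied, an anatomical side-consistency constraint resolves the
    remaining front/back identity ambiguity: the fore-limb cannon pair
    fixes the facing direction, and the anterior (posterior) body-length
    and oblique landmarks are searched on that (the opposite) side of the
    box centre.  Returns (batch, K, 3) arrays of (x, y, confidence) in
    input-frame pixels.
    """
    scale = raw_outputs[0]  # finest stride
    stride = scale["stride"]
    kpt = _to_array(scale["kpt"])
    n = kpt.shape[0]
    h, w = kpt.shape[-2:]
    kk = kpt.reshape(n, num_keypoints, 3, h, w)
    conf = _sigmoid(kk[:, :, 2])  # (n, K, h, w)
    out = np.empty((n, num_keypoints, 3))
    cell_x = (np.arange(w) + 0.5) * stride
    for bi in range(n):
        for k in range(num_keypoints):
            out[bi, k] = _peak_vote(kk, conf, bi, k, stride, h, w)
        if box is not None and num_keypoints > max(_CANNON_KPS):
            bcx = (box[0] + box[2]) / 2.0
            front_x = np.mean([out[bi, k, 0] for k in _CANNON_KPS])
            facing_left = front_x < bcx
            left_mask = np.broadcast_to(cell_x < bcx, (h, w))
            for k in _ANTERIOR_KPS:
                mask = left_mask if facing_left else ~left_mask
                out[bi, k] = _peak_vote(kk, conf, bi, k, stride, h, w, mask=mask)
            for k in _POSTERIOR_KPS:
                mask = ~left_mask if facing_left else left_mask
                out[bi, k] = _peak_vote(kk, conf, bi, k, stride, h, w, mask=mask)
    return out


def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def nms(candidates: list[dict], iou_threshold: float = 0.6) -> list[dict]:
    kept = []
    for cand in sorted(candidates, key=lambda c: -c["score"]):
        if all(box_iou(cand["box"], k["box"]) < iou_threshold for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# target assignment + loss
# ---------------------------------------------------------------------------


def _assign_targets(box_px, kps_px, strides, grids, reg_max):
    """Box-positive cells (3x3 around the box centre) per eligible stride."""
    x1, y1, x2, y2 = box_px
    targets = []  # (scale_idx, iy, ix, ltrb)
    for si, (stride, (gh, gw)) in enumerate(zip(strides, grids)):
        bx, by = (x1 + x2) / 2 / stride, (y1 + y2) / 2 / stride
        half_w, half_h = (x2 - x1) / 2 / stride, (y2 - y1) / 2 / stride
        if max(half_w, half_h) > reg_max - 1:
            continue  # this stride cannot represent the box
        cx0, cy0 = int(bx), int(by)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ix, iy = cx0 + dx, cy0 + dy
                if not (0 <= ix < gw and 0 <= iy < gh):
                    continue
                ccx, ccy = ix + 0.5, iy + 0.5
                ltrb = np.array([ccx - x1 / stride, ccy - y1 / stride, x2 / stride - ccx, y2 / stride - ccy])
                if ltrb.min() < 0 or ltrb.max() > reg_max - 1:
                    continue
                targets.append((si, iy, ix, ltrb))
    return targets


def _assign_keypoint_cells(kps_px, strides, grids):
    """Local keypoint cells: for each keypoint and stride, the 2x2 cells
    nearest its location (bilinear neighbourhood), with the exact offset
    from each cell centre.  A tight neighbourhood keeps the presence maps
    of nearby landmarks discriminative; global identity ambiguities are
    resolved structurally at decode time."""
    out = []  # per scale: (k_idx, iy, ix, off_x, off_y)
    for stride, (gh, gw) in zip(strides, grids):
        rows = []
        for k, (kx, ky) in enumerate(kps_px[:, :2]):
            gx, gy = kx / stride - 0.5, ky / stride - 0.5
            x0, y0 = int(np.floor(gx)), int(np.floor(gy))
            for iy in (y0, y0 + 1):
                for ix in (x0, x0 + 1):
                    if not (0 <= ix < gw and 0 <= iy < gh):
                        continue
                    rows.append((k, iy, ix, kx / stride - (ix + 0.5), ky / stride - (iy + 0.5)))
        out.append(rows)
    return out


def _ciou_loss(pred_xyxy, gt_xyxy):
    """Complete-IoU loss on tape tensors; inputs (P, 4)."""
    px1, py1, px2, py2 = (pred_xyxy[:, i] for i in range(4))
    gx1, gy1, gx2, gy2 = (Tensor(gt_xyxy[:, i]) for i in range(4))
    iw = T.maximum(T.minimum(px2, gx2) - T.maximum(px1, gx1), 0.0)
    ih = T.maximum(T.minimum(py2, gy2) - T.maximum(py1, gy1), 0.0)
    inter = iw * ih
    pa = T.maximum(px2 - px1, 1e-6) * T.maximum(py2 - py1, 1e-6)
    ga = (gx2 - gx1) * (gy2 - gy1)
    union = pa + ga - inter
    iou = inter / (union + 1e-9)
    # enclosing box diagonal + centre distance
    ex = T.maximum(px2, gx2) - T.minimum(px1, gx1)
    ey = T.maximum(py2, gy2) - T.minimum(py1, gy1)
    c2 = ex * ex + ey * ey + 1e-9
    dx = (px1 + px2 - gx1 - gx2) * 0.5
    dy = (py1 + py2 - gy1 - gy2) * 0.5
    rho2 = dx * dx + dy * dy
    v = (4.0 / math.pi**2) * (T.arctan((gx2 - gx1) / (gy2 - gy1 + 1e-9)) - T.arctan((px2 - px1) / (py2 - py1 + 1e-9))) ** 2
    alpha = (v / (1.0 - iou + v + 1e-9)).detach()
    return (1.0 - iou + rho2 / c2 + alpha * v).mean()


def _bce_with_logits(z, y):
    return (T.softplus(z) - z * y).mean()


@dataclass
class LossWeights:
    cls: float = 1.0
    box: float = 5.0
    kpt: float = 10.0  # local offsets, O(1) cell units
    kpt_conf: float = 2.0  # per-keypoint presence maps
    pos_weight: float = 20.0  # class-imbalance boost for positive cells


def pose_loss(raw_outputs, batch_targets, reg_max, num_keypoints, weights: LossWeights = LossWeights()):
    """Composite loss over one batch.

    ``batch_targets[i]`` holds the box-cell list from
    :func:`_assign_targets` (``cells``), the per-scale keypoint cells from
    :func:`_assign_keypoint_cells` (``kpt_cells``) and the ground-truth
    ``box``.
    """
    total_cls = None
    n_scales = len(raw_outputs)
    box_terms, kpt_terms, kptc_terms = [], [], []
    for si, scale in enumerate(raw_outputs):
        cls = scale["cls"]
        n, _, h, w = cls.shape
        stride = scale["stride"]

        # -- class map + box regression at box-positive cells -------------
        y = np.zeros((n, 1, h, w), dtype=np.float32)
        wmap = np.ones((n, 1, h, w), dtype=np.float32)
        pos = []  # (bi, iy, ix, box)
        for bi, tgt in enumerate(batch_targets):
            for (tsi, iy, ix, _ltrb) in tgt["cells"]:
                if tsi != si:
                    continue
                y[bi, 0, iy, ix] = 1.0
                wmap[bi, 0, iy, ix] = weights.pos_weight
                pos.append((bi, iy, ix, tgt["box"]))
        bce = (T.softplus(cls) - cls * Tensor(y)) * Tensor(wmap)
        scale_cls = bce.mean()
        total_cls = scale_cls if total_cls is None else total_cls + scale_cls
        if pos:
            b_idx = np.array([p[0] for p in pos])
            iy_idx = np.array([p[1] for p in pos])
            ix_idx = np.array([p[2] for p in pos])
            gt_boxes = np.stack([p[3] for p in pos]).astype(np.float32)
            box_map = scale["box"][(b_idx, slice(None), iy_idx, ix_idx)]  # (P, 4*reg_max)
            prob = T.softmax(box_map.reshape(len(pos), 4, reg_max), axis=-1)
            ltrb_pred = (prob * Tensor(np.arange(reg_max, dtype=np.float32))).sum(axis=-1)
            ccx = (ix_idx + 0.5).astype(np.float32)
            ccy = (iy_idx + 0.5).astype(np.float32)
            px1 = (Tensor(ccx) - ltrb_pred[:, 0]) * stride
            py1 = (Tensor(ccy) - ltrb_pred[:, 1]) * stride
            px2 = (Tensor(ccx) + ltrb_pred[:, 2]) * stride
            py2 = (Tensor(ccy) + ltrb_pred[:, 3]) * stride
            pred_xyxy = T.concat([p.reshape(len(pos), 1) for p in (px1, py1, px2, py2)], axis=1)
            box_terms.append(_ciou_loss(pred_xyxy, gt_boxes))

        # -- per-keypoint presence maps + local offsets --------------------
        kk = scale["kpt"].reshape(n, num_keypoints, 3, h, w)
        conf_y = np.zeros((n, num_keypoints, h, w), dtype=np.float32)
        conf_w = np.ones((n, num_keypoints, h, w), dtype=np.float32)
        kcells = []  # (bi, k, iy, ix, off_x, off_y)
        for bi, tgt in enumerate(batch_targets):
            for (k, iy, ix, off_x, off_y) in tgt["kpt_cells"][si]:
                conf_y[bi, k, iy, ix] = 1.0
                conf_w[bi, k, iy, ix] = weights.pos_weight
                kcells.append((bi, k, iy, ix, off_x, off_y))
        logits = kk[:, :, 2]
        kptc_terms.append((((T.softplus(logits) - logits * Tensor(conf_y)) * Tensor(conf_w)).mean()))
        if kcells:
            b_idx = np.array([c[0] for c in kcells])
            k_idx = np.array([c[1] for c in kcells])
            iy_idx = np.array([c[2] for c in kcells])
            ix_idx = np.array([c[3] for c in kcells])
            gt_off = np.array([[c[4], c[5]] for c in kcells], dtype=np.float32)
            pred_off = kk[(b_idx, k_idx, slice(0, 2), iy_idx, ix_idx)]  # (P, 2)
            kpt_terms.append(((pred_off - Tensor(gt_off)) ** 2).mean())

    loss = total_cls * (weights.cls / n_scales)
    parts = {"cls": float(loss.data)}
    if box_terms:
        box_l = box_terms[0]
        for t_ in box_terms[1:]:
            box_l = box_l + t_
        loss = loss + box_l * (weights.box / len(box_terms))
        parts["box"] = float(box_l.data) / len(box_terms)
    if kptc_terms:
        kc = kptc_terms[0]
        for t_ in kptc_terms[1:]:
            kc = kc + t_
        loss = loss + kc * (weights.kpt_conf / len(kptc_terms))
        parts["kpt_conf"] = float(kc.data) / len(kptc_terms)
    if kpt_terms:
        kpt_l = kpt_terms[0]
        for t_ in kpt_terms[1:]:
            kpt_l = kpt_l + t_
        loss = loss + kpt_l * (weights.kpt / len(kpt_terms))
        parts["kpt"] = float(kpt_l.data) / len(kpt_terms)
    parts["total"] = float(loss.data)
    return loss, parts


# ---------------------------------------------------------------------------
# trainer + estimator facade
# ---------------------------------------------------------------------------


@dataclass
class PoseTrainConfig:
    """Training hyper-parameters.  The full-scale defaults follow the
    published protocol (SGD, batch 16, 200 epochs, 640 px); CPU-scale runs
    override epochs/size/optimizer explicitly."""

    optimizer: str = "sgd"
    lr: float = 0.01
    momentum: float = 0.937
    batch_size: int = 16
    epochs: int = 200
    input_size: int = 640
    conf_threshold: float = 0.25
    nms_iou: float = 0.6
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    val_every: int = 5
    hflip_prob: float = 0.5  # online mirror augmentation during training


def _load_sample(image_path, ann_path, input_size):
    import imageio.v3 as iio

    ann = read_labelme(ann_path)
    img = iio.imread(image_path)
    lb = Letterbox(ann.image_size, input_size)
    x = lb.apply(img).astype(np.float32) / 255.0
    kps = lb.to_input(ann.keypoints.as_array(with_visibility=False))
    x1, y1 = lb.to_input(np.array([ann.box[:2]]))[0]
    x2, y2 = lb.to_input(np.array([ann.box[2:]]))[0]
    return {
        "image": x.transpose(2, 0, 1),
        "box": np.array([x1, y1, x2, y2], dtype=np.float32),
        "kps": kps.astype(np.float32),
        "letterbox": lb,
        "ann": ann,
    }


class PoseDetector:
    """Estimator facade: ``fit`` on a manifest, ``predict`` per image.

    Follows the sklearn protocol shape (``get_params``/``set_params`` via
    construction args, fitted state in ``model_``/``history_``) even though
    the inputs are image manifests rather than feature matrices.
    """

    def __init__(self, model_config: ModelConfig | None = None, train_config: PoseTrainConfig | None = None,
                 seed: int = 0):
        self.model_config = model_config or ModelConfig.preset("ep", scale="tiny-test")
        self.train_config = train_config or PoseTrainConfig()
        self.seed = seed

    def get_params(self, deep=True):
        return {"model_config": self.model_config, "train_config": self.train_config, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- training ----------------------------------------------------------
    def fit(self, train_manifest: pd.DataFrame, val_manifest: pd.DataFrame | None = None):
        cfg, tc = self.model_config, self.train_config
        if len(train_manifest) == 0:
            raise ValueError("training manifest is empty")
        size = tc.input_size
        model = build_model(cfg, seed=tc.seed)
        samples = [_load_sample(r["image"], r["annotation"], size) for _, r in train_manifest.iterrows()]
        val_samples = (
            [_load_sample(r["image"], r["annotation"], size) for _, r in val_manifest.iterrows()]
            if val_manifest is not None and len(val_manifest)
            else []
        )
        strides = (8, 16, 32)
        grids = [(size // s, size // s) for s in strides]
        for s in samples:
            s["cells"] = _assign_targets(s["box"], s["kps"], strides, grids, model.reg_max)
            s["kpt_cells"] = _assign_keypoint_cells(s["kps"], strides, grids)

        params = model.parameters()
        if tc.optimizer == "sgd":
            opt = SGD(params, lr=tc.lr, momentum=tc.momentum)
        elif tc.optimizer == "adam":
            opt = Adam(params, lr=tc.lr)
        else:
            raise ValueError(f"unknown optimizer {tc.optimizer!r}")
        rng = np.random.default_rng(tc.seed)
        history = {"loss": [], "val_map": [], "val_pck": []}
        best = ((-np.inf, -np.inf), None)
        n = len(samples)
        for epoch in range(tc.epochs):
            # cosine decay to 5% of the base rate over the epoch budget
            opt.lr = tc.lr * (0.05 + 0.95 * 0.5 * (1 + math.cos(math.pi * epoch / tc.epochs)))
            model.train()
            order = rng.permutation(n)
            epoch_losses = []
            for lo in range(0, n, tc.batch_size):
                idx = order[lo : lo + tc.batch_size]
                imgs, tgts = [], []
                for i in idx:
                    s = samples[i]
                    if rng.random() < tc.hflip_prob:
                        img = s["image"][:, :, ::-1].copy()
                        x1, y1, x2, y2 = s["box"]
                        fbox = np.array([size - 1 - x2, y1, size - 1 - x1, y2], dtype=np.float32)
                        fkps = s["kps"].copy()
                        fkps[:, 0] = size - 1 - fkps[:, 0]
                        tgts.append({
                            "cells": _assign_targets(fbox, fkps, strides, grids, model.reg_max),
                            "kpt_cells": _assign_keypoint_cells(fkps, strides, grids),
                            "box": fbox,
                        })
                        imgs.append(img)
                    else:
                        imgs.append(s["image"])
                        tgts.append(s)
                xb = np.stack(imgs)
                raw = model.forward(xb)
                loss, parts = pose_loss(raw, tgts, model.reg_max, cfg.num_keypoints, tc.loss_weights)
                if not np.isfinite(parts["total"]):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}: {parts}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(parts["total"])
            history["loss"].append(float(np.mean(epoch_losses)))
            if val_samples and ((epoch + 1) % tc.val_every == 0 or epoch == tc.epochs - 1):
                vm, vp = self._validate(model, val_samples, tc)
                history["val_map"].append((epoch, vm))
                history["val_pck"].append((epoch, vp))
                # best by val mAP; PCK breaks ties (mAP saturates at 0 early on)
                if (vm, vp) > best[0]:
                    best = ((vm, vp), model.state_dict())
        if best[1] is not None:
            model.load_state_dict(best[1])
        model.eval()
        self.model_ = model
        self.history_ = history
        self.input_size_ = size
        return self

    def _validate(self, model, val_samples, tc):
        from ..evaluation import detection_metrics

        model.eval()
        dets, gts = [], []
        for s in val_samples:
            raw = model.forward(s["image"][None])
            cands = nms(decode_predictions(raw, model.reg_max, conf_threshold=tc.conf_threshold)[0], tc.nms_iou)
            kps = decode_keypoints(raw, self.model_config.num_keypoints,
                                   box=cands[0]["box"] if cands else None)[0]
            dets.append([{"score": c["score"], "kps": kps} for c in cands[:1]])
            gts.append([{"kps": np.column_stack([s["kps"], np.full(len(s["kps"]), 2.0)]), "box": s["box"]}])
        m = detection_metrics(dets, gts)
        return m.map_oks, m.mean_pck

    # -- inference ---------------------------------------------------------
    def predict(self, image: np.ndarray, conf_threshold: float | None = None, nms_iou: float | None = None,
                tta: bool = False) -> Detection | None:
        """Best detection mapped back to original pixels, or ``None`` when
        nothing clears the confidence threshold (an explicit no-animal
        outcome, not an error).  With ``tta`` the image and its mirror are
        both decoded and the keypoint estimates averaged (keypoint
        identities are orientation-free, so the mirror maps straight back)."""
        if tta:
            direct = self.predict(image, conf_threshold, nms_iou, tta=False)
            mirrored = self.predict(np.asarray(image)[:, ::-1].copy(), conf_threshold, nms_iou, tta=False)
            if direct is None or mirrored is None:
                return direct
            w_img = np.asarray(image).shape[1]
            back = mirrored.kps_array().copy()
            back[:, 0] = w_img - 1 - back[:, 0]
            avg = (direct.kps_array() + back) / 2.0
            vis = direct.keypoints.as_array()[:, 2]
            return Detection(
                box=direct.box,
                score=max(direct.score, mirrored.score),
                keypoints=KeypointSet.from_array(np.column_stack([avg, vis])),
                keypoint_conf=(direct.keypoint_conf + mirrored.keypoint_conf) / 2.0,
            )
        model = self.model_
        tc = self.train_config
        conf = tc.conf_threshold if conf_threshold is None else conf_threshold
        iou = tc.nms_iou if nms_iou is None else nms_iou
        lb = Letterbox(image.shape[:2], self.input_size_)
        x = (lb.apply(image).astype(np.float32) / 255.0).transpose(2, 0, 1)
        model.eval()
        raw = model.forward(x[None])
        cands = nms(decode_predictions(raw, model.reg_max, conf_threshold=conf)[0], iou)
        if not cands:
            return None
        best = cands[0]
        kps_in = decode_keypoints(raw, self.model_config.num_keypoints, box=best["box"])[0]
        kps_orig = lb.to_original(kps_in[:, :2])
        box = np.concatenate([lb.to_original(np.array([best["box"][:2]]))[0], lb.to_original(np.array([best["box"][2:]]))[0]])
        # estimates exist for all keypoints; per-point quality lives in
        # keypoint_conf rather than the visibility flag
        vis = np.full(len(kps_in), 2)
        return Detection(
            box=tuple(box),
            score=best["score"],
            keypoints=KeypointSet.from_array(np.column_stack([kps_orig, vis])),
            keypoint_conf=kps_in[:, 2],
        )


def train_pose(model_config: ModelConfig, train_manifest, val_manifest=None, hyper: PoseTrainConfig | None = None) -> PoseDetector:
    """Functional wrapper over :class:`PoseDetector.fit`."""
    det = PoseDetector(model_config=model_config, train_config=hyper or PoseTrainConfig())
    return det.fit(train_manifest, val_manifest)


def infer_keypoints(detector: PoseDetector, image, conf_threshold=0.25, nms_iou=0.6) -> Detection | None:
    return detector.predict(image, conf_threshold=conf_threshold, nms_iou=nms_iou)
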