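"""Calibrated keypoint-distance features: the detection->regression bridge.

A reference ruler of known physical length fixes the pixel-to-metre scale of
each image; Euclidean distances between designated keypoint pairs, expressed
in centimetres, form the feature vector for measurement regression.  Two
pair sets are supported: ``named5`` (the five pairs that define the target
measurements) and ``all_pairs`` (all C(10,2)=45 distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import KEYPOINT_NAMES, NAMED_PAIRS, AnnotatedImage, CalibrationError, KeypointSet

ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(KEYPOINT_NAMES, 2))


class MissingFeatureError(ValueError):
    """A keypoint required by the pair set is not visible."""


@dataclass
class CalibrationScale:
    pixels_per_meter: float
    ruler_endpoints: np.ndarray
    ruler_length_m: float

    def __post_init__(self):
        self.ruler_endpoints = np.asarray(self.ruler_endpoints, dtype=float).reshape(2, 2)
        implied = float(np.linalg.norm(self.ruler_endpoints[1] - self.ruler_endpoints[0])) / self.ruler_length_m
        if abs(implied - self.pixels_per_meter) * self.ruler_length_m > 0.5:
            raise CalibrationError(
                f"scale {self.pixels_per_meter:.3f} px/m inconsistent with endpoints ({implied:.3f} px/m)"
            )


def pixels_per_meter(ruler_endpoints, ruler_length_m: float = 1.1) -> CalibrationScale:
    """Scale from the imaged ruler: pixel distance / physical length."""
    ends = np.asarray(ruler_endpoints, dtype=float).reshape(2, 2)
    if ruler_length_m <= 0:
        raise CalibrationError("ruler length must be positive")
    dist = float(np.linalg.norm(ends[1] - ends[0]))
    if dist < 1e-9:
        raise CalibrationError("ruler endpoints coincide")
    return CalibrationScale(dist / ruler_length_m, ends, ruler_length_m)


def pair_names(mode: str) -> list[str]:
    if mode == "named5":
        return list(NAMED_PAIRS)
    if mode == "all_pairs":
        return [f"{a}__{b}" for a, b in ALL_PAIRS]
    raise ValueError(f"unknown pair-set mode {mode!r}")


def distance_features(kps: KeypointSet, scale: CalibrationScale, mode: str = "named5") -> np.ndarray:
    """Ordered distances in cm: ``100 * ||p_i - p_j|| / pixels_per_meter``.

    A required-but-invisible keypoint raises :class:`MissingFeatureError`
    naming the offending pair (missing values propagate; they are never
    silently imputed).
    """
    pairs = list(NAMED_PAIRS.values()) if mode == "named5" else list(ALL_PAIRS)
    out = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        if not (kps.visible(a) and kps.visible(b)):
            raise MissingFeatureError(f"keypoint pair ({a}, {b}) is not fully visible")
        out[i] = 100.0 * kps.distance(a, b) / scale.pixels_per_meter
    return out


def features_from_annotation(ann: AnnotatedImage, mode: str = "named5") -> np.ndarray:
    scale = pixels_per_meter(ann.ruler_endpoints, ann.ruler_length_m)
    return distance_features(ann.keypoints, scale, mode=mode)


def feature_table(annotations, mode: str = "named5") -> pd.DataFrame:
    """``image_id, individual_id, <pair columns>`` for a list of annotations."""
    rows = []
    cols = pair_names(mode)
    for ann in annotations:
        feats = features_from_annotation(ann, mode=mode)
        rows.append({"image_id": ann.image_path, "individual_id": ann.individual_id, **dict(zip(cols, feats))})
    return pd.DataFrame(rows)


class FeatureNormalizer(BaseEstimator, TransformerMixin):
    """Per-dimension z-scoring with statistics frozen on the training split.

    ``transform``/``inverse_transform`` are exact inverses; a zero-variance
    training dimension raises, naming the dimension, rather than dividing
    by an epsilon.
    """

    def __init__(self, feature_names=None):
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 2:
            raise ValueError("need a 2-D array with at least two training vectors")
        if np.isnan(X).any():
            raise ValueError("training vectors contain missing entries")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        dead = np.nonzero(self.scale_ <= 0)[0]
        if len(dead):
            names = (
                [self.feature_names[i] for i in dead]
                if self.feature_names is not None
                else dead.tolist()
            )
            raise ValueError(f"zero-variance feature dimension(s): {names}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return X * self.scale_ + self.mean_


def fit_normalizer(train_vectors, feature_names=None) -> FeatureNormalizer:
    return FeatureNormalizer(feature_names=feature_names).fit(train_vectors)
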