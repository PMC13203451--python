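"""End-to-end two-stage pipeline: detect keypoints -> calibrate -> regress.

Stage one localises the ten body-surface keypoints with the pose network;
stage two converts them to ruler-calibrated distance features and predicts
the five measurements with a regression model trained on the *detected*
features of the training split (so systematic detector bias is absorbed by
the regressor).  Per-individual estimates average the per-view predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import read_labelme
from .core import MEASUREMENT_FIELDS, AnnotatedImage
from .morphometry import distance_features, pair_names, pixels_per_meter
from .posenet import ModelConfig, PoseDetector, PoseTrainConfig
from .regression import MeasurementRegressor


@dataclass
class PipelineConfig:
    feature_mode: str = "named5"
    conf_threshold: float = 0.1
    tta: bool = True  # flip-averaged keypoint decoding at inference
    regressor_kwargs: dict = field(default_factory=lambda: {"architecture": "transformer", "weight_decay": 1e-2, "dropout": 0.0})
    seed: int = 0


class TwoStagePipeline:
    """Detector + calibrated-distance regressor, trained jointly on a manifest.

    ``fit`` expects manifest DataFrames (``image``, ``annotation``,
    ``individual_id`` columns) for the train and validation splits and a
    measurement table indexed by individual.  The ruler calibration is read
    from each image's annotation; detection failures fall back to the
    annotated keypoints of the training split (never of the test split,
    where they raise instead), so a rare miss cannot silently poison
    training.
    """

    def __init__(self, model_config: ModelConfig | None = None, train_config: PoseTrainConfig | None = None,
                 config: PipelineConfig | None = None):
        self.model_config = model_config or ModelConfig.preset("ep", scale="tiny-test", input_size=160)
        self.train_config = train_config or PoseTrainConfig(
            optimizer="adam", lr=3e-3, batch_size=8, epochs=40, input_size=160, val_every=5
        )
        self.config = config or PipelineConfig()

    # -- feature extraction -------------------------------------------------
    def _detect_features(self, manifest: pd.DataFrame, allow_fallback: bool) -> pd.DataFrame:
        import imageio.v3 as iio

        rows = []
        for _, r in manifest.iterrows():
            ann = read_labelme(r["annotation"])
            det = self.detector_.predict(iio.imread(r["image"]), conf_threshold=self.config.conf_threshold, tta=self.config.tta)
            scale = pixels_per_meter(ann.ruler_endpoints, ann.ruler_length_m)
            if det is None:
                if not allow_fallback:
                    raise RuntimeError(f"no animal detected in {r['image']}")
                kps = ann.keypoints
            else:
                kps = det.keypoints
            feats = distance_features(kps, scale, mode=self.config.feature_mode)
            rows.append({"image_id": r["image"], "individual_id": r["individual_id"],
                         **dict(zip(pair_names(self.config.feature_mode), feats))})
        return pd.DataFrame(rows)

    def _targets(self, feats: pd.DataFrame, measurements: pd.DataFrame) -> np.ndarray:
        return measurements.loc[feats["individual_id"], list(MEASUREMENT_FIELDS)].to_numpy(dtype=float)

    # -- training -----------------------------------------------------------
    def fit(self, train_manifest: pd.DataFrame, val_manifest: pd.DataFrame, measurements: pd.DataFrame):
        cfgseed = self.config.seed
        self.train_config.seed = cfgseed
        self.detector_ = PoseDetector(self.model_config, self.train_config, seed=cfgseed)
        self.detector_.fit(train_manifest, val_manifest)
        f_train = self._detect_features(train_manifest, allow_fallback=True)
        f_val = self._detect_features(val_manifest, allow_fallback=True)
        cols = pair_names(self.config.feature_mode)
        self.feature_columns_ = cols
        # the detector partially memorises its training images, so train-split
        # features understate test-time noise; estimate per-feature noise on
        # the validation split and inject it while fitting the regressor
        from .annotations import read_labelme as _read
        from .morphometry import features_from_annotation

        ann_val = np.stack(
            [features_from_annotation(_read(r["annotation"]), mode=self.config.feature_mode)
             for _, r in val_manifest.iterrows()]
        )
        resid = f_val[cols].to_numpy(dtype=float) - ann_val
        # robust scale (MAD): a few gross detection failures must not inflate
        # the injected noise and wash out otherwise-informative features
        noise_sd = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=0)), axis=0)
        self.feature_noise_sd_ = noise_sd
        self.regressor_ = MeasurementRegressor(
            seed=cfgseed, noise_sigma=noise_sd, **self.config.regressor_kwargs
        )
        # augment the regression training set with the annotated train-split
        # features: clean rows anchor the allometric structure, detected rows
        # (plus injected noise) teach robustness to detector error
        ann_train = np.stack(
            [features_from_annotation(_read(r["annotation"]), mode=self.config.feature_mode)
             for _, r in train_manifest.iterrows()]
        )
        X_fit = np.vstack([f_train[cols].to_numpy(dtype=float), ann_train])
        y_fit = np.vstack([self._targets(f_train, measurements)] * 2)
        self.regressor_.fit(
            X_fit, y_fit,
            X_val=f_val[cols].to_numpy(dtype=float), y_val=self._targets(f_val, measurements),
        )
        return self

    # -- prediction ---------------------------------------------------------
    def predict_manifest(self, manifest: pd.DataFrame, per_individual: bool = True) -> pd.DataFrame:
        feats = self._detect_features(manifest, allow_fallback=False)
        if per_individual:
            # denoise the regressor input: per-individual median of the
            # per-view features (robust to a single bad detection), then
            # one prediction per individual
            feats = feats.groupby("individual_id")[self.feature_columns_].median().reset_index()
        preds = self.regressor_.predict(feats[self.feature_columns_].to_numpy(dtype=float))
        out = pd.DataFrame(preds, columns=list(MEASUREMENT_FIELDS))
        out.insert(0, "individual_id", feats["individual_id"].to_numpy())
        return out

    def predict_images(self, images, annotations: list[AnnotatedImage]) -> np.ndarray:
        """Predict from in-memory images with known ruler annotations
        (used by the perturbation-robustness harness, where the image is
        modified photometrically but the scene geometry is unchanged)."""
        rows = []
        for img, ann in zip(images, annotations):
            det = self.detector_.predict(np.asarray(img), conf_threshold=self.config.conf_threshold, tta=self.config.tta)
            if det is None:
                raise RuntimeError("no animal detected in perturbed image")
            scale = pixels_per_meter(ann.ruler_endpoints, ann.ruler_length_m)
            rows.append(distance_features(det.keypoints, scale, mode=self.config.feature_mode))
        return self.regressor_.predict(np.asarray(rows))

    def evaluate(self, test_manifest: pd.DataFrame, measurements: pd.DataFrame):
        from .evaluation import regression_metrics

        pred = self.predict_manifest(test_manifest, per_individual=True)
        truth = measurements.loc[pred["individual_id"], list(MEASUREMENT_FIELDS)].to_numpy(dtype=float)
        return regression_metrics(pred[list(MEASUREMENT_FIELDS)].to_numpy(), truth)
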