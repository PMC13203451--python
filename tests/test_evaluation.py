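"""Metric identities, OKS/PR oracles, perturbations and harnesses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphopose.evaluation import (
    PairingError,
    PerturbationSpec,
    ablation_table,
    detection_metrics,
    default_perturbations,
    oks,
    pck,
    perturb,
    regression_metrics,
    robustness_report,
    split_stability,
)


class TestRegressionMetrics:
    def test_perfect_prediction(self, rng):
        t = rng.uniform(50, 200, (10, 5))
        m = regression_metrics(t, t)
        assert (m.rmse, m.mae, m.mape_percent, m.r2) == (0.0, 0.0, 0.0, 1.0)

    def test_constant_offset(self, rng):
        t = rng.uniform(50, 200, (10, 5))
        m = regression_metrics(t + 2.0, t)
        assert m.mae == pytest.approx(2.0) and m.rmse == pytest.approx(2.0)

    def test_three_point_hand_table(self):
        t = np.array([[10.0], [20.0], [30.0]])
        p = np.array([[12.0], [18.0], [33.0]])
        m = regression_metrics(p, t)
        assert m.rmse == pytest.approx(np.sqrt((4 + 4 + 9) / 3), abs=1e-9)
        assert m.mae == pytest.approx(7 / 3, abs=1e-9)
        assert m.mape_percent == pytest.approx(100 * (0.2 + 0.1 + 0.1) / 3, abs=1e-9)
        assert m.r2 == pytest.approx(1 - 17 / 200, abs=1e-9)

    def test_length_mismatch_and_zero_truth_rejected(self, rng):
        t = rng.uniform(50, 200, (5, 5))
        with pytest.raises(PairingError):
            regression_metrics(t[:4], t)
        t0 = t.copy()
        t0[0, 0] = 0.0
        with pytest.raises(ValueError):
            regression_metrics(t, t0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(10, 100, (8, 5))
        p = t + rng.standard_normal((8, 5))
        m = regression_metrics(p, t)
        assert m.rmse >= m.mae >= 0 and m.r2 <= 1


class TestOKS:
    def box(self):
        return (0.0, 0.0, 100.0, 50.0)

    def test_exact_match_gives_one(self, rng):
        gt = np.column_stack([rng.uniform(0, 100, (10, 2)), np.full(10, 2)])
        assert oks(gt[:, :2], gt, self.box()) == pytest.approx(1.0)

    def test_single_point_closed_form(self):
        gt = np.array([[50.0, 25.0, 2.0]] + [[0, 0, 0]] * 9)
        s = np.sqrt(100.0 * 50.0)
        k = 0.05
        d = s * k * np.sqrt(2)
        det = gt[:, :2].copy()
        det[0, 0] += d
        assert oks(det, gt, self.box(), k=k) == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_matches_independent_formula(self, rng):
        gt = np.column_stack([rng.uniform(0, 100, (10, 2)), np.full(10, 2)])
        det = gt[:, :2] + rng.standard_normal((10, 2)) * 3
        k = 0.05
        s2 = 100.0 * 50.0
        expected = np.mean([np.exp(-((det[i] - gt[i, :2]) ** 2).sum() / (2 * s2 * k * k)) for i in range(10)])
        assert oks(det, gt, self.box(), k=k) == pytest.approx(expected, rel=1e-9)

    def test_no_visible_points_is_undefined(self):
        gt = np.zeros((10, 3))
        with pytest.raises(ValueError):
            oks(gt[:, :2], gt, self.box())


class TestDetectionMetrics:
    def _gt(self, rng, n):
        gts = []
        for _ in range(n):
            kps = np.column_stack([rng.uniform(10, 90, (10, 2)), np.full(10, 2)])
            gts.append([{"kps": kps, "box": (0.0, 0.0, 100.0, 100.0)}])
        return gts

    def test_perfect_detector_scores_one(self, rng):
        gts = self._gt(rng, 20)
        dets = [[{"score": 0.9, "kps": g[0]["kps"][:, :2]}] for g in gts]
        m = detection_metrics(dets, gts)
        assert m.map_oks == pytest.approx(1.0)
        assert m.precision == pytest.approx(1.0) and m.recall == pytest.approx(1.0)
        assert m.mean_pck == pytest.approx(1.0)

    def test_silent_detector_has_zero_recall(self, rng):
        gts = self._gt(rng, 5)
        m = detection_metrics([[] for _ in gts], gts)
        assert m.recall == 0.0 and m.map_oks == 0.0

    def test_hand_enumerated_pr_with_false_positive_and_miss(self, rng):
        """5 images; 4 correct hits, 1 miss, plus 1 high-scoring FP:
        precision 4/5, recall 4/5, AP50 by the interpolated PR curve."""
        gts = self._gt(rng, 5)
        dets = [[{"score": 0.8, "kps": g[0]["kps"][:, :2]}] for g in gts[:4]]
        far = gts[4][0]["kps"][:, :2] + 500.0
        dets.append([{"score": 0.9, "kps": far}])
        m = detection_metrics(dets, gts)
        assert m.precision == pytest.approx(0.8) and m.recall == pytest.approx(0.8)
        # ranked: FP(0.9), then 4 TPs -> precision envelope 4/5 up to recall 0.8
        assert m.ap50 == pytest.approx(0.8 * 0.8)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(PairingError):
            detection_metrics([[]], [[], []])


class TestPerturbations:
    def test_unit_brightness_gain_is_identity(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        assert np.array_equal(perturb(img, PerturbationSpec("brightness", 1.0)), img)

    def test_brightness_outside_band_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec("brightness", 1.5).validate()
        with pytest.raises(ValueError):
            PerturbationSpec("occlusion", 1.0).validate()

    def test_motion_blur_preserves_interior_mean(self, rng):
        img = rng.uniform(50, 200, (64, 64)).astype(np.float64)
        out = perturb(img, PerturbationSpec("motion_blur", 9))
        inner = (slice(8, -8), slice(8, -8))
        assert abs(out[inner].mean() - img[inner].mean()) / img[inner].mean() < 0.005

    def test_noise_sd_matches_request(self):
        img = np.full((200, 200), 120.0)
        out = perturb(img, PerturbationSpec("gaussian_noise", 10.0), seed=1)
        assert abs((out - img).std() - 10.0) / 10.0 < 0.05

    def test_occlusion_patch_area_fraction(self, rng):
        img = rng.uniform(0, 255, (100, 100, 3))  # textured, so the fill shows
        out = perturb(img, PerturbationSpec("occlusion", 0.1), seed=3)
        changed = (out != img).any(axis=-1).mean()
        assert 0.05 < changed <= 0.15


class TestHarnesses:
    def _fake_pipeline(self, truth):
        def pipeline(images):
            # prediction error grows with photometric distance from baseline
            out = []
            for img, t in zip(images, truth):
                drift = abs(float(np.asarray(img, dtype=float).mean()) - 128.0) / 128.0
                out.append(t + drift * 5.0 + 1.0)
            return np.asarray(out)

        return pipeline

    def test_robustness_report_rows_and_null_condition(self, rng):
        truth = rng.uniform(80, 200, (6, 5))
        images = [np.full((32, 32, 3), 128, dtype=np.uint8) for _ in range(6)]
        report = robustness_report(self._fake_pipeline(truth), images, truth,
                                   specs=default_perturbations(), seed=0)
        assert len(report) == 5
        null = robustness_report(self._fake_pipeline(truth), images, truth,
                                 specs=[PerturbationSpec("brightness", 1.0)], seed=0)
        assert null.iloc[0]["rmse"] == pytest.approx(null.iloc[1]["rmse"])

    def test_split_stability_rows_and_identical_seeds(self):
        calls = []

        def builder(split, seed):
            calls.append(seed)
            from morphopose.evaluation import RegressionMetrics

            rng = np.random.default_rng(seed)
            t = rng.uniform(50, 200, (8, 5))
            return regression_metrics(t + rng.standard_normal((8, 5)) * 0.1, t)

        ids = [f"i{k}" for k in range(30)]
        df = split_stability(builder, ids, seeds=[3, 3, 5])
        assert len(df) == 3 + 2  # three seeds + range + sd rows
        assert df.iloc[0]["r2"] == pytest.approx(df.iloc[1]["r2"])

    def test_ablation_table_flags_and_complexity(self):
        df = ablation_table(scale="nano", input_size=640)
        assert list(df["preset"]) == ["E0", "E1", "E2", "E3", "EP"]
        assert df.loc[df.preset == "E0", ["uib", "senetv2", "ta"]].to_numpy().tolist() == [[False, False, False]]
        assert df.loc[df.preset == "EP", ["uib", "senetv2", "ta"]].to_numpy().tolist() == [[True, True, True]]
        assert df.loc[df.preset == "EP", "params"].item() < df.loc[df.preset == "E0", "params"].item()
        df2 = ablation_table(scale="nano", input_size=640)
        pd.testing.assert_frame_equal(df, df2)
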