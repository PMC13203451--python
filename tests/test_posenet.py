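"""Architecture contracts, complexity accounting and the training loop."""

import numpy as np
import pytest

from morphopose._engine import SGD, Tensor
from morphopose.posenet import (
    ModelConfig,
    PoseTrainConfig,
    PoseDetector,
    build_model,
    complexity,
    count_macs,
    decode_predictions,
    nms,
)


TINY = dict(scale="tiny-test", input_size=160)


class TestBuild:
    def test_ablation_presets_are_nameable(self):
        flags = {n: ModelConfig.preset(n) for n in ("e0", "e1", "e2", "e3", "ep")}
        assert (flags["e0"].use_uib, flags["e0"].use_se, flags["e0"].use_ta) == (False, False, False)
        assert (flags["ep"].use_uib, flags["ep"].use_se, flags["ep"].use_ta) == (True, True, True)
        assert flags["e1"].use_uib and not flags["e1"].use_se
        with pytest.raises(ValueError):
            ModelConfig.preset("e9")

    def test_switched_off_insertions_recover_baseline_graph(self, rng):
        base = build_model(ModelConfig.preset("e0", **TINY), seed=4)
        off = build_model(ModelConfig.preset("ep", **TINY, use_uib=False, use_se=False, use_ta=False), seed=4)
        sd_a, sd_b = base.state_dict(), off.state_dict()
        assert sd_a.keys() == sd_b.keys()
        assert all(np.array_equal(sd_a[k], sd_b[k]) for k in sd_a)
        x = rng.standard_normal((1, 3, 96, 96)).astype(np.float32)
        base.eval(), off.eval()
        ya, yb = base.forward(x), off.forward(x)
        assert np.array_equal(ya[0]["cls"].data, yb[0]["cls"].data)

    def test_forward_emits_three_scales_with_strides(self):
        model = build_model(ModelConfig.preset("ep", **TINY), seed=0)
        model.eval()
        out = model.forward(np.zeros((1, 3, 160, 160), dtype=np.float32))
        assert [o["stride"] for o in out] == [8, 16, 32]
        assert [o["cls"].shape[-1] for o in out] == [20, 10, 5]
        assert out[0]["kpt"].shape[1] == 30  # 10 keypoints x (dx, dy, conf)

    def test_indivisible_input_rejected(self):
        model = build_model(ModelConfig.preset("e0", **TINY), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 150, 150), dtype=np.float32))

    def test_seeded_init_is_deterministic(self):
        a = build_model(ModelConfig.preset("ep", **TINY), seed=9)
        b = build_model(ModelConfig.preset("ep", **TINY), seed=9)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a.parameters(), b.parameters()))


class TestComplexity:
    def test_single_conv_macs_closed_form(self):
        # one 3x3 conv layer 3->16 at 64x64, stride 1: k^2*Cin*Cout*H*W MACs
        from morphopose._engine import conv as conv_mod
        from morphopose.attention import ConvBN

        layer = ConvBN(3, 16, 3, 1)
        layer.eval()
        conv_mod.MAC_TRACE = []
        layer(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        macs = sum(conv_mod.MAC_TRACE)
        conv_mod.MAC_TRACE = None
        assert macs == 9 * 3 * 16 * 64 * 64

    def test_gflops_scale_quadratically_with_input_side(self):
        model = build_model(ModelConfig.preset("e0", **TINY), seed=0)
        assert count_macs(model, 640) == pytest.approx(4 * count_macs(model, 320), rel=1e-9)

    def test_width_increase_strictly_increases_parameters(self):
        tiny = build_model(ModelConfig.preset("e0", **TINY), seed=0)
        nano = build_model(ModelConfig.preset("e0"), seed=0)
        assert nano.num_params() > tiny.num_params()

    def test_full_model_params_fewer_than_baseline_at_nano(self):
        e0 = complexity(build_model(ModelConfig.preset("e0"), seed=0), 640)
        ep = complexity(build_model(ModelConfig.preset("ep"), seed=0), 640)
        assert ep.params < e0.params
        assert ep.params_mb == pytest.approx(ep.params * 4 / 2**20)
        assert ep.model_size_mb == pytest.approx(ep.params_mb / 2)


class TestDecodeAndNMS:
    def _fake_outputs(self, conf_map, reg_max=4, nkpt=10):
        h, w = conf_map.shape
        return [{
            "cls": conf_map.reshape(1, 1, h, w).astype(np.float32),
            "box": np.zeros((1, 4 * reg_max, h, w), np.float32),
            "kpt": np.zeros((1, 3 * nkpt, h, w), np.float32),
            "stride": 8,
        }]

    def test_decode_respects_confidence_threshold(self):
        conf = np.full((4, 4), -10.0)
        conf[1, 2] = 10.0  # sigmoid ~ 1
        cands = decode_predictions(self._fake_outputs(conf), reg_max=4, num_keypoints=10, conf_threshold=0.5)[0]
        assert len(cands) == 1 and cands[0]["score"] > 0.99

    def test_uniform_box_logits_decode_to_bin_mean(self):
        conf = np.full((2, 2), 10.0)
        cands = decode_predictions(self._fake_outputs(conf), reg_max=4, num_keypoints=10, conf_threshold=0.5)[0]
        x1, y1, x2, y2 = cands[0]["box"]
        # uniform softmax over bins 0..3 -> expectation 1.5 cells each side
        assert (x2 - x1) == pytest.approx(2 * 1.5 * 8)

    def test_nms_suppresses_overlapping_candidates(self):
        a = {"box": (0, 0, 10, 10), "score": 0.9, "kps": np.zeros((10, 3))}
        b = {"box": (1, 1, 11, 11), "score": 0.8, "kps": np.zeros((10, 3))}
        c = {"box": (50, 50, 60, 60), "score": 0.7, "kps": np.zeros((10, 3))}
        kept = nms([a, b, c], iou_threshold=0.5)
        assert [k["score"] for k in kept] == [0.9, 0.7]


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, small_dataset):
        cfg = ModelConfig.preset("e0", **TINY)
        tc = PoseTrainConfig(optimizer="sgd", lr=0.0, momentum=0.0, batch_size=4, epochs=1,
                             input_size=96, val_every=10, hflip_prob=0.0)
        det = PoseDetector(cfg, tc)
        before = [p.data.copy() for p in build_model(cfg, seed=tc.seed).parameters()]
        det.fit(small_dataset["manifest"].iloc[:4])
        after = det.model_.parameters()
        same = [np.array_equal(b, a.data) for b, a in zip(before, after)]
        # conv/linear weights untouched; BN running stats are buffers, not parameters
        assert all(same)

    def test_training_reduces_loss(self, small_dataset):
        cfg = ModelConfig.preset("ep", **TINY)
        tc = PoseTrainConfig(optimizer="adam", lr=3e-3, batch_size=4, epochs=4, input_size=96, val_every=10)
        det = PoseDetector(cfg, tc).fit(small_dataset["manifest"])
        assert det.history_["loss"][-1] < det.history_["loss"][0]

    def test_empty_manifest_rejected(self, small_dataset):
        import pandas as pd

        with pytest.raises(ValueError):
            PoseDetector(ModelConfig.preset("e0", **TINY)).fit(pd.DataFrame(columns=["image", "annotation"]))

    def test_predict_returns_detection_or_none(self, small_dataset):
        import imageio.v3 as iio
        from morphopose.posenet import Detection

        cfg = ModelConfig.preset("e0", **TINY)
        tc = PoseTrainConfig(optimizer="adam", lr=3e-3, batch_size=4, epochs=1, input_size=96, val_every=10)
        det = PoseDetector(cfg, tc).fit(small_dataset["manifest"].iloc[:4])
        img = iio.imread(small_dataset["manifest"].iloc[0]["image"])
        result = det.predict(img, conf_threshold=0.25)
        assert result is None or isinstance(result, Detection)
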