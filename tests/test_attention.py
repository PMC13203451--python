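"""Scalar hand-oracles for the three attention transforms and drop-in
contracts of their host blocks."""

import numpy as np
import pytest

from morphopose._engine import Tensor
from morphopose.attention import (
    C2PSA,
    C3k2,
    SENetV2,
    SEConfig,
    SPPF,
    TAConfig,
    TripleAttention,
    UIB,
    UIBConfig,
    se_recalibrate,
    triple_attention,
    uib_block,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestUIB:
    def test_shape_contract_and_hidden_width(self, rng):
        m = UIB(8, 8, expand=2.0, rng=rng)
        assert m.expand_conv.conv.weight.shape[0] == 16
        x = rng.standard_normal((1, 8, 16, 16))
        assert uib_block(x, UIBConfig(8), module=m).shape == (1, 8, 16, 16)

    def test_zero_input_gives_zero_pre_residual_output(self, rng):
        m = UIB(4, 4, expand=1.5, residual=False, rng=rng)
        m.eval()
        y = m(Tensor(np.zeros((1, 4, 6, 6))))
        # BN in eval mode with zero running stats keeps zeros; SiLU(0) = 0
        assert np.allclose(y.data, 0.0)

    def test_scalar_composition_oracle(self):
        """1x1 channels, 1x1 spatial, hand-set unit kernels: the block is the
        scalar chain silu(w_c * silu(w_e * x)) (BN initialised to identity in
        eval mode, depthwise 3x3 sees the centre tap only)."""
        m = UIB(1, 1, expand=1.0, residual=False, rng=np.random.default_rng(0))
        m.expand_conv.conv.weight.data = np.full((1, 1, 1, 1), 2.0, dtype=np.float32)
        m.dw_conv.conv.weight.data = np.zeros((1, 1, 3, 3), dtype=np.float32)
        m.dw_conv.conv.weight.data[0, 0, 1, 1] = 3.0
        m.project_conv.conv.weight.data = np.full((1, 1, 1, 1), 0.5, dtype=np.float32)
        m.eval()
        x = 1.7
        silu = lambda v: v * _sigmoid(v)
        expect = silu(0.5 * (3.0 * silu(2.0 * x)))
        y = m(Tensor(np.full((1, 1, 1, 1), x, dtype=np.float32)))
        assert y.data.ravel()[0] == pytest.approx(expect, rel=2e-3)  # BN eps

    def test_invalid_expand_rejected(self):
        with pytest.raises(ValueError):
            UIB(4, 4, expand=0.0)


class TestSENetV2:
    def test_constant_channel_squeeze_is_its_value(self, rng):
        """z_c is the spatial mean, so a constant channel squeezes to v."""
        from morphopose._engine.conv import global_avg_pool

        x = np.full((1, 3, 5, 7), 0.0)
        x[0, 1] = 4.25
        z = global_avg_pool(Tensor(x))
        assert np.allclose(z.data, [[0.0, 4.25, 0.0]])

    def test_gate_never_amplifies(self, rng):
        m = SENetV2(8, reduction=4, branches=2, rng=rng)
        x = rng.standard_normal((2, 8, 6, 6))
        y = se_recalibrate(x, SEConfig(8, 4, 2), module=m)
        assert np.all(np.abs(y).max(axis=(2, 3)) <= np.abs(x).max(axis=(2, 3)) + 1e-12)

    def test_single_branch_matches_hand_evaluation(self):
        """C=2, H=W=1, hand-set weights, ReLU bottleneck: follows the SE
        chain squeeze -> W2 relu(W1 z) -> sigmoid -> scale exactly."""
        m = SENetV2(2, reduction=1, branches=1, rng=np.random.default_rng(0))
        W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        W2 = np.array([[2.0, 0.0], [1.0, 1.0]])
        m.fc1[0].weight.data = W1
        m.fc1[0].bias.data = np.zeros(2)
        m.fc2[0].weight.data = W2
        m.fc2[0].bias.data = np.zeros(2)
        x = np.array([3.0, -2.0])
        z = x  # H=W=1
        s = _sigmoid(np.maximum(z @ W1, 0.0) @ W2)
        expect = s * x
        y = se_recalibrate(x.reshape(1, 2, 1, 1), SEConfig(2, 1, 1), module=m)
        assert np.allclose(y.ravel(), expect, atol=1e-6)

    def test_reduction_larger_than_channels_rejected(self):
        with pytest.raises(ValueError):
            SENetV2(4, reduction=8)


class TestTripleAttention:
    def test_branch_isolation_with_unit_weight(self, rng):
        m = TripleAttention(k=3, gammas=(1.0, 0.0, 0.0), rng=rng)
        m.eval()
        x = rng.standard_normal((1, 4, 5, 5))
        full = m(Tensor(np.asarray(x, dtype=np.float64))).data
        chan = m.channel(Tensor(x.transpose(0, 2, 1, 3))).data.transpose(0, 2, 1, 3)
        assert np.allclose(full, chan, atol=1e-12)

    def test_constant_input_gives_constant_multiple_in_interior(self, rng):
        # zero padding makes border gates differ; interior gates are constant
        m = TripleAttention(k=3, rng=rng)
        m.eval()
        x = np.full((1, 3, 6, 6), 2.0)
        y = triple_attention(x, TAConfig(kernel=3), module=m)
        inner = y[:, 1:-1, 2:-2, 2:-2]
        assert np.allclose(inner, inner.ravel()[0])

    def test_fusion_equals_weighted_branch_sum(self, rng):
        m = TripleAttention(k=3, gammas=(0.2, 0.5, 0.3), rng=rng)
        m.eval()
        x = rng.standard_normal((1, 2, 3, 3))
        xt = Tensor(x)
        a_s = m.spatial(xt).data
        a_c = m.channel(Tensor(x.transpose(0, 2, 1, 3))).data.transpose(0, 2, 1, 3)
        a_d = m.directional(Tensor(x.transpose(0, 3, 2, 1))).data.transpose(0, 3, 2, 1)
        expect = 0.2 * a_c + 0.5 * a_s + 0.3 * a_d
        assert np.allclose(m(xt).data, expect, atol=1e-6)

    def test_fixed_gammas_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TripleAttention(gammas=(0.5, 0.5, 0.5))

    def test_small_spatial_sizes_are_padded_not_rejected(self, rng):
        m = TripleAttention(k=7, rng=rng)
        m.eval()
        x = rng.standard_normal((1, 2, 3, 3))
        assert m(Tensor(x)).shape == (1, 2, 3, 3)


class TestHostBlocks:
    def test_c3k2_without_uib_equals_baseline_bit_for_bit(self, rng):
        a = C3k2(16, 16, n=1, use_uib=False, rng=np.random.default_rng(3))
        b = C3k2(16, 16, n=1, use_uib=False, rng=np.random.default_rng(3))
        a.eval(), b.eval()
        x = Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
        assert np.array_equal(a(x).data, b(x).data)

    def test_sppf_shape_contract(self, rng):
        m = SPPF(16, 16, use_se=True, se_reduction=4, rng=np.random.default_rng(0))
        m.eval()
        assert m(Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))).shape == (1, 16, 8, 8)

    def test_se_insertion_is_a_pure_addition(self):
        """Same seed: the SPPF host weights are identical with and without
        the SE insertion, so switching it off recovers the baseline."""
        plain = SPPF(16, 16, use_se=False, rng=np.random.default_rng(5))
        with_se = SPPF(16, 16, use_se=True, se_reduction=4, rng=np.random.default_rng(5))
        assert np.array_equal(plain.cv1.conv.weight.data, with_se.cv1.conv.weight.data)
        assert np.array_equal(plain.cv2.conv.weight.data, with_se.cv2.conv.weight.data)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 16, 8, 8)).astype(np.float32))
        plain.eval(), with_se.eval()
        se = with_se.se
        with_se.se = None
        assert np.array_equal(plain(x).data, with_se(x).data)
        with_se.se = se

    def test_c2psa_ta_parameter_bookkeeping(self):
        base = C2PSA(32, 32, n=1, use_ta=False, rng=np.random.default_rng(2))
        with_ta = C2PSA(32, 32, n=1, use_ta=True, ta_kernel=7, rng=np.random.default_rng(2))
        ta_params = sum(p.data.size for p in TripleAttention(7).parameters())
        assert with_ta.num_params() == base.num_params() + ta_params

    def test_c2psa_requires_matching_channels(self):
        with pytest.raises(ValueError):
            C2PSA(32, 64)
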