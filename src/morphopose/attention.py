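"""Attention mechanisms and their host blocks.

Three feature-map transforms are provided, each a drop-in insertion into a
standard YOLO11 host block:

* :class:`UIB` — universal inverted bottleneck ("channel expansion →
  depthwise separable convolution → channel compression"), hosted inside
  :class:`C3k2` in place of its dense bottlenecks;
* :class:`SENetV2` — squeeze-and-excitation channel recalibration with ``b``
  parallel excitation branches (``b=1`` is classic SE), hosted after the
  :class:`SPPF` output projection;
* :class:`TripleAttention` — three-branch gating over rotated tensor views
  (spatial, channel–height, channel–width), hosted on the attention path of
  :class:`C2PSA`.

All blocks preserve the host block's tensor contract, and switching an
insertion off recovers the unmodified host bit-for-bit given shared weights.
Hidden widths and split ratios of the hosts follow the published YOLO11
layouts so that parameter and FLOP accounting is comparable with printed
model cards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._engine import T, BatchNorm2d, Conv2d, Module, Tensor
from ._engine.conv import conv2d, global_avg_pool, max_pool2d


def _chunk2(x, c):
    """Split (N, 2c, H, W) into two c-channel halves."""
    return x[:, :c], x[:, c : 2 * c]


class ConvBN(Module):
    """Conv2d (no bias) + BatchNorm + activation — the YOLO 'Conv' unit."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return T.silu(y) if self.act else y


# ---------------------------------------------------------------------------
# the three attention mechanisms
# ---------------------------------------------------------------------------


class UIB(Module):
    """Universal inverted bottleneck.

    ``y = act_out(W_proj(BN(W_dw(act(W_exp(x)))))) [+ x]`` with a pointwise
    expansion to ``ceil(expand * c1)`` channels, a depthwise ``k x k``
    convolution, and a pointwise compression.  The outer nonlinearity is the
    block's output activation (SiLU); a sigmoid there would crush the
    residual feature scale.  Residual connection when shapes allow.
    """

    def __init__(self, c1, c2, expand: float = 2.0, k: int = 3, residual: bool = True, rng=None):
        super().__init__()
        if expand <= 0:
            raise ValueError(f"expand ratio must be positive, got {expand}")
        if k % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        ch = int(np.ceil(expand * c1))
        self.expand_conv = ConvBN(c1, ch, 1, rng=rng)  # We + psi
        self.dw_conv = ConvBN(ch, ch, k, g=ch, act=False, rng=rng)  # Wd + phi
        self.project_conv = ConvBN(ch, c2, 1, act=False, rng=rng)  # Wc
        self.residual = residual and c1 == c2

    def forward(self, x):
        y = T.silu(self.project_conv(self.dw_conv(self.expand_conv(x))))
        return x + y if self.residual else y


class SENetV2(Module):
    """Multi-branch squeeze-and-excitation channel recalibration.

    squeeze:   ``z_c = mean_{i,j} X_c(i, j)``
    excite:    per branch ``W2 . relu(W1 . z)``; branch outputs averaged
    gate:      ``s = sigmoid(.)``, ``Y_c = s_c * X_c``

    With ``branches=1`` this is exactly the classic SE recalibration.
    """

    def __init__(self, channels: int, reduction: int = 16, branches: int = 2, rng=None):
        super().__init__()
        if reduction < 1 or reduction > channels:
            raise ValueError(f"reduction must be in [1, {channels}], got {reduction}")
        if branches < 1:
            raise ValueError("need at least one excitation branch")
        hidden = int(np.ceil(channels / reduction))
        rng = rng or np.random.default_rng(0)
        from ._engine import Linear

        self.fc1 = [Linear(channels, hidden, rng=rng) for _ in range(branches)]
        self.fc2 = [Linear(hidden, channels, rng=rng) for _ in range(branches)]

    def forward(self, x):
        z = global_avg_pool(x)  # (N, C)
        logits = None
        for w1, w2 in zip(self.fc1, self.fc2):
            branch = w2(T.relu(w1(z)))
            logits = branch if logits is None else logits + branch
        s = T.sigmoid(logits * (1.0 / len(self.fc1)))
        return x * s.reshape(s.shape[0], s.shape[1], 1, 1)


class _GateBranch(Module):
    """Z-pool (max + mean over channel axis) -> conv -> sigmoid gate."""

    def __init__(self, k=7, rng=None):
        super().__init__()
        self.conv = Conv2d(2, 1, k, 1, k // 2, bias=False, rng=rng)
        self.bn = BatchNorm2d(1)

    def forward(self, x):
        pooled = T.concat([T.tmax(x, axis=1, keepdims=True), x.mean(axis=1, keepdims=True)], axis=1)
        return x * T.sigmoid(self.bn(self.conv(pooled)))


class TripleAttention(Module):
    """Three-branch rotated gating: ``Y = gc*Ac(X) + gs*As(X) + gd*Ad(X)``.

    * spatial branch ``As``: gate over the (H, W) plane;
    * channel branch ``Ac``: rotate C<->H, gate, rotate back;
    * directional branch ``Ad``: rotate C<->W, gate, rotate back.

    Fusion weights default to fixed 1/3 each (the plain branch average);
    ``learnable=True`` makes them trainable via a softmax parameterisation
    so they stay positive and sum to one.
    """

    def __init__(self, k: int = 7, gammas: Sequence[float] = (1 / 3, 1 / 3, 1 / 3), learnable: bool = False, rng=None):
        super().__init__()
        gammas = np.asarray(gammas, dtype=np.float32)
        if not learnable and abs(float(gammas.sum()) - 1.0) > 1e-6:
            raise ValueError("fixed fusion weights must sum to 1")
        self.spatial = _GateBranch(k, rng=rng)
        self.channel = _GateBranch(k, rng=rng)
        self.directional = _GateBranch(k, rng=rng)
        self.learnable = learnable
        if learnable:
            self.gamma_logits = Tensor(np.log(np.maximum(gammas, 1e-6)), requires_grad=True)
        else:
            self._gammas = gammas

    def fusion_weights(self):
        if self.learnable:
            return T.softmax(self.gamma_logits, axis=0)
        return Tensor(self._gammas)

    def forward(self, x):
        g = self.fusion_weights()
        a_s = self.spatial(x)
        a_c = self.channel(x.transpose(0, 2, 1, 3)).transpose(0, 2, 1, 3)
        a_d = self.directional(x.transpose(0, 3, 2, 1)).transpose(0, 3, 2, 1)
        return a_c * g[0] + a_s * g[1] + a_d * g[2]


# ---------------------------------------------------------------------------
# host blocks
# ---------------------------------------------------------------------------


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, g=1, k=(3, 3), e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBN(c1, c_, k[0], 1, rng=rng)
        self.cv2 = ConvBN(c_, c2, k[1], 1, g=g, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    """CSP bottleneck stack with a 3x3 kernel (C3 layout)."""

    def __init__(self, c1, c2, n=2, shortcut=True, g=1, e=0.5, use_uib=False, uib_expand=2.0, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBN(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBN(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBN(2 * c_, c2, 1, rng=rng)
        if use_uib:
            self.m = [UIB(c_, c_, expand=uib_expand, rng=rng) for _ in range(n)]
        else:
            self.m = [Bottleneck(c_, c_, shortcut, g, k=(3, 3), e=1.0, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        for m in self.m:
            y = m(y)
        return self.cv3(T.concat([y, self.cv2(x)], axis=1))


class C3k2(Module):
    """C2f-style split/grow block; hosts UIB when ``use_uib`` is set."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, g=1, shortcut=True, use_uib=False, uib_expand=2.0, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBN(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBN((2 + n) * self.c, c2, 1, rng=rng)
        self.m = []
        for _ in range(n):
            if c3k:
                self.m.append(C3k(self.c, self.c, 2, shortcut, g, use_uib=use_uib, uib_expand=uib_expand, rng=rng))
            elif use_uib:
                self.m.append(UIB(self.c, self.c, expand=uib_expand, rng=rng))
            else:
                self.m.append(Bottleneck(self.c, self.c, shortcut, g, rng=rng))

    def forward(self, x):
        a, b = _chunk2(self.cv1(x), self.c)
        ys = [a, b]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(T.concat(ys, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast); hosts SENetV2 on its output."""

    def __init__(self, c1, c2, k=5, use_se=False, se_reduction=16, se_branches=2, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBN(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBN(c_ * 4, c2, 1, 1, rng=rng)
        self.k = k
        self.se = SENetV2(c2, se_reduction, se_branches, rng=rng) if use_se else None

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(max_pool2d(y[-1], self.k, 1, self.k // 2))
        out = self.cv2(T.concat(y, axis=1))
        return self.se(out) if self.se is not None else out


class PSAAttention(Module):
    """Position-sensitive spatial self-attention over flattened H*W tokens."""

    def __init__(self, dim, num_heads, attn_ratio=0.5, rng=None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = ConvBN(dim, h, 1, act=False, rng=rng)
        self.proj = ConvBN(dim, dim, 1, act=False, rng=rng)
        self.pe = ConvBN(dim, dim, 3, 1, g=dim, act=False, rng=rng)

    def forward(self, x):
        n, c, hh, ww = x.shape
        npos = hh * ww
        qkv = self.qkv(x).reshape(n, self.num_heads, self.key_dim * 2 + self.head_dim, npos)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim : 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim :]
        attn = T.softmax((q.transpose(0, 1, 3, 2) @ k) * self.scale, axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(n, c, hh, ww)
        out = out + self.pe(v.reshape(n, c, hh, ww))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c, num_heads, rng=None):
        super().__init__()
        self.attn = PSAAttention(c, num_heads, rng=rng)
        self.ffn1 = ConvBN(c, c * 2, 1, rng=rng)
        self.ffn2 = ConvBN(c * 2, c, 1, act=False, rng=rng)

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn2(self.ffn1(x))


class C2PSA(Module):
    """Partial self-attention block; hosts TripleAttention on the attention path."""

    def __init__(self, c1, c2, n=1, e=0.5, use_ta=False, ta_kernel=7, ta_learnable=False, rng=None):
        super().__init__()
        if c1 != c2:
            raise ValueError("C2PSA requires matching input/output channels")
        self.c = int(c1 * e)
        self.cv1 = ConvBN(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBN(2 * self.c, c1, 1, rng=rng)
        self.m = [PSABlock(self.c, max(1, self.c // 64), rng=rng) for _ in range(n)]
        self.ta = TripleAttention(ta_kernel, learnable=ta_learnable, rng=rng) if use_ta else None

    def forward(self, x):
        a, b = _chunk2(self.cv1(x), self.c)
        for m in self.m:
            b = m(b)
        if self.ta is not None:
            b = self.ta(b)
        return self.cv2(T.concat([a, b], axis=1))


# ---------------------------------------------------------------------------
# functional wrappers (array in, array out) used by the equation-level tests
# ---------------------------------------------------------------------------


@dataclass
class UIBConfig:
    in_channels: int
    out_channels: int | None = None
    expand_ratio: float = 2.0
    kernel: int = 3
    residual: bool = True
    seed: int = 0


@dataclass
class SEConfig:
    channels: int
    reduction: int = 16
    branches: int = 2
    seed: int = 0


@dataclass
class TAConfig:
    kernel: int = 7
    gammas: tuple = (1 / 3, 1 / 3, 1 / 3)
    learnable: bool = False
    seed: int = 0


def _run(module: Module, x: np.ndarray) -> np.ndarray:
    module.eval()
    return module(Tensor(np.asarray(x, dtype=np.float64))).data


def uib_block(x: np.ndarray, cfg: UIBConfig, module: UIB | None = None) -> np.ndarray:
    """Apply a UIB transform to a feature map (eval mode)."""
    if x.ndim != 4 or x.shape[1] != cfg.in_channels:
        raise ValueError(f"expected (N,{cfg.in_channels},H,W), got {x.shape}")
    if module is None:
        module = UIB(
            cfg.in_channels,
            cfg.out_channels or cfg.in_channels,
            cfg.expand_ratio,
            cfg.kernel,
            cfg.residual,
            rng=np.random.default_rng(cfg.seed),
        )
    return _run(module, x)


def se_recalibrate(x: np.ndarray, cfg: SEConfig, module: SENetV2 | None = None) -> np.ndarray:
    """Apply SE(NetV2) channel recalibration to a feature map."""
    if x.ndim != 4 or x.shape[1] != cfg.channels:
        raise ValueError(f"expected (N,{cfg.channels},H,W), got {x.shape}")
    if module is None:
        module = SENetV2(cfg.channels, cfg.reduction, cfg.branches, rng=np.random.default_rng(cfg.seed))
    return _run(module, x)


def triple_attention(x: np.ndarray, cfg: TAConfig, module: TripleAttention | None = None) -> np.ndarray:
    """Apply TripleAttention fusion to a feature map."""
    if np.ndim(x) != 4:
        raise ValueError("feature map must be rank 4 (N, C, H, W)")
    if module is None:
        module = TripleAttention(cfg.kernel, cfg.gammas, cfg.learnable, rng=np.random.default_rng(cfg.seed))
    return _run(module, x)
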