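"""Assembly of the single-class keypoint-detection network.

The backbone/neck follow the published YOLO11 layout (C3k2 stacks, SPPF,
C2PSA, three-scale P3/P4/P5 head); the pose head carries box-regression
(distribution-focal bins), class and keypoint branches per scale.  Three
attention insertions are switchable per :class:`ModelConfig`:

========  =============================  ==========================
flag      mechanism                      host
========  =============================  ==========================
use_uib   universal inverted bottleneck  C3k2 bottlenecks
use_se    SENetV2 recalibration          SPPF output
use_ta    TripleAttention                C2PSA attention path
========  =============================  ==========================

The five ablation presets are E0 (none), E1 (UIB), E2 (SE), E3 (TA) and
Ep (all three).  Turning a switch off recovers the baseline graph
bit-for-bit under a shared seed, because insertion points wrap the host
blocks without re-ordering their parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .._engine import T, Conv2d, Module, Tensor
from .._engine.conv import upsample_nearest2
from ..attention import C2PSA, C3k2, ConvBN, SPPF

KEYPOINT_COUNT = 10

_ABLATION_PRESETS = {
    "e0": (False, False, False),
    "e1": (True, False, False),
    "e2": (False, True, False),
    "e3": (False, False, True),
    "ep": (True, True, True),
}


def load_base_config() -> dict:
    text = resources.files("morphopose.configs").joinpath("yolo11_pose.yaml").read_text()
    return yaml.safe_load(text)


def make_divisible(x: float, divisor: int) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclass
class ModelConfig:
    """Network scale preset plus ablation switches."""

    scale: str = "nano"
    use_uib: bool = False
    use_se: bool = False
    use_ta: bool = False
    num_keypoints: int = KEYPOINT_COUNT
    num_classes: int = 1
    input_size: int | None = None  # None -> scale default
    uib_layers: tuple = ()
    uib_expand: float = 1.25
    se_reduction: int = 16
    se_branches: int = 2
    ta_kernel: int = 7
    ta_learnable: bool = False

    @classmethod
    def preset(cls, name: str, scale: str = "nano", **overrides) -> "ModelConfig":
        key = name.lower()
        if key not in _ABLATION_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_ABLATION_PRESETS)}")
        uib, se, ta = _ABLATION_PRESETS[key]
        base = load_base_config()
        ins = base["insertions"]
        cfg = cls(
            scale=scale,
            use_uib=uib,
            use_se=se,
            use_ta=ta,
            uib_layers=tuple(ins["uib_layers"]),
            uib_expand=float(ins["uib_expand"]),
            se_reduction=int(ins["se_reduction"]),
            se_branches=int(ins["se_branches"]),
            ta_kernel=int(ins["ta_kernel"]),
        )
        return replace(cfg, **overrides)

    def resolved_input_size(self) -> int:
        if self.input_size is not None:
            return self.input_size
        return int(load_base_config()["scales"][self.scale]["input_size"])


class _Upsample(Module):
    def forward(self, x):
        return upsample_nearest2(x)


class _Concat(Module):
    def forward(self, xs):
        return T.concat(xs, axis=1)


class PoseHead(Module):
    """Per-scale box (4*reg_max bins), class and keypoint branches.

    Branch widths follow the published head: box width
    ``max(16, ch[0]//4, 4*reg_max)``, class width ``max(ch[0], min(nc,100))``
    with depthwise separable stages, keypoint width ``max(ch[0]//4, 3*nkpt)``.
    """

    def __init__(self, nc, nkpt, ch, reg_max=16, rng=None):
        super().__init__()
        self.nc, self.nkpt, self.reg_max = nc, nkpt, reg_max
        self.nl = len(ch)
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        c4 = max(ch[0] // 4, nkpt * 3)
        self.box_branches, self.cls_branches, self.kpt_branches = [], [], []
        for x in ch:
            self.box_branches.append(
                _Branch(
                    [ConvBN(x, c2, 3, rng=rng), ConvBN(c2, c2, 3, rng=rng)],
                    Conv2d(c2, 4 * reg_max, 1, rng=rng),
                )
            )
            self.cls_branches.append(
                _Branch(
                    [
                        ConvBN(x, x, 3, g=x, rng=rng),
                        ConvBN(x, c3, 1, rng=rng),
                        ConvBN(c3, c3, 3, g=c3, rng=rng),
                        ConvBN(c3, c3, 1, rng=rng),
                    ],
                    Conv2d(c3, nc, 1, rng=rng),
                )
            )
            self.kpt_branches.append(
                _Branch(
                    [ConvBN(x, c4, 3, rng=rng), ConvBN(c4, c4, 3, rng=rng)],
                    Conv2d(c4, nkpt * 3, 1, rng=rng),
                )
            )
        # distribution-focal projection onto bin indices; fixed, not trained
        self.dfl_bins = Tensor(np.arange(reg_max, dtype=np.float32))

    def forward(self, feats):
        out = []
        for i, f in enumerate(feats):
            out.append(
                {
                    "box": self.box_branches[i](f),
                    "cls": self.cls_branches[i](f),
                    "kpt": self.kpt_branches[i](f),
                    "stride": self.strides[i],
                }
            )
        return out


class _Branch(Module):
    def __init__(self, stem, final):
        super().__init__()
        self.stem = stem
        self.final = final

    def forward(self, x):
        for m in self.stem:
            x = m(x)
        return self.final(x)


class PoseModel(Module):
    """Layer-graph network built from the YAML row spec."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        base = load_base_config()
        if cfg.scale not in base["scales"]:
            raise ValueError(f"unknown scale {cfg.scale!r}")
        sc = base["scales"][cfg.scale]
        depth, width = float(sc["depth"]), float(sc["width"])
        max_ch, divisor = int(sc["max_channels"]), int(sc["divisor"])
        self.reg_max = int(sc["reg_max"])
        self.max_stride = 32
        rng = np.random.default_rng(seed)

        rows = list(base["backbone"]) + list(base["head"])
        self.rows = rows
        self.layers: list[Module] = []
        self.froms: list = []
        ch: list[int] = []
        out_ch = 3
        for idx, (frm, repeats, kind, args) in enumerate(rows):
            n = max(round(repeats * depth), 1) if repeats > 1 else repeats
            uib_here = cfg.use_uib and idx in cfg.uib_layers
            if kind == "conv":
                c2 = make_divisible(min(args[0], max_ch) * width, divisor)
                mod = ConvBN(ch[frm] if ch else 3, c2, args[1], args[2], rng=rng)
                out_ch = c2
            elif kind == "c3k2":
                c2 = make_divisible(min(args[0], max_ch) * width, divisor)
                c3k = bool(args[1])
                e = float(args[2]) if len(args) > 2 else 0.5
                mod = C3k2(
                    ch[frm], c2, n=n, c3k=c3k, e=e,
                    use_uib=uib_here, uib_expand=cfg.uib_expand, rng=rng,
                )
                out_ch = c2
            elif kind == "sppf":
                c2 = make_divisible(min(args[0], max_ch) * width, divisor)
                mod = SPPF(
                    ch[frm], c2, args[1],
                    use_se=cfg.use_se, se_reduction=cfg.se_reduction,
                    se_branches=cfg.se_branches, rng=rng,
                )
                out_ch = c2
            elif kind == "c2psa":
                c2 = make_divisible(min(args[0], max_ch) * width, divisor)
                mod = C2PSA(
                    ch[frm], c2, n=n,
                    use_ta=cfg.use_ta, ta_kernel=cfg.ta_kernel,
                    ta_learnable=cfg.ta_learnable, rng=rng,
                )
                out_ch = c2
            elif kind == "upsample":
                mod = _Upsample()
            elif kind == "concat":
                mod = _Concat()
                out_ch = sum(ch[f] for f in frm)
            elif kind == "pose_head":
                mod = PoseHead(
                    cfg.num_classes, cfg.num_keypoints,
                    [ch[f] for f in frm], reg_max=self.reg_max, rng=rng,
                )
            else:
                raise ValueError(f"unknown module kind {kind!r} in model config")
            self.layers.append(mod)
            self.froms.append(frm)
            ch.append(out_ch)
        self.channels = ch
        needed = set()
        for frm in self.froms:
            if isinstance(frm, list):
                needed.update(f for f in frm if f != -1)
        self.save = needed

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x.astype(np.float32, copy=False))
        h, w = x.shape[-2:]
        if h % self.max_stride or w % self.max_stride:
            raise ValueError(f"input size {h}x{w} must be divisible by {self.max_stride}")
        outputs: dict[int, Tensor] = {}
        y = x
        for idx, (mod, frm) in enumerate(zip(self.layers, self.froms)):
            if isinstance(frm, list):
                inp = [y if f == -1 else outputs[f] for f in frm]
                y = mod(inp) if isinstance(mod, (_Concat, PoseHead)) else mod(*inp)
            else:
                y = mod(y if frm == -1 else outputs[frm])
            if idx in self.save:
                outputs[idx] = y
        return y


def build_model(cfg: ModelConfig, seed: int = 0) -> PoseModel:
    """Build the network for ``cfg`` with deterministic seeded init."""
    return PoseModel(cfg, seed=seed)
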