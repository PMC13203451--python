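"""Parameter and FLOP accounting for built models.

Parameters are enumerated exactly over trainable tensors.  FLOPs follow the
fused-convolution MAC convention used by common profilers (and by published
YOLO model cards): each convolution contributes
``k^2 * C_in/groups * C_out * H_out * W_out`` multiply-accumulates, one MAC
counts as two FLOPs, batch-norm is folded into the convolution, and
activations, pooling, concatenation and attention matrix products are not
counted.  Because the network is fully convolutional, per-layer output areas
scale exactly with input area, so the count is traced once at a small
reference size and rescaled to the requested input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._engine import conv as _conv
from .architecture import ModelConfig, PoseModel, build_model

_TRACE_SIZE = 64  # smallest comfortable multiple of the maximum stride


@dataclass
class ComplexityReport:
    params: int
    params_mb: float  # float32 storage: count * 4 bytes, in MiB
    model_size_mb: float  # float16 checkpoint payload: count * 2 bytes, in MiB
    gflops: float  # at ``input_size``, MACs x 2

    def as_dict(self) -> dict:
        return {
            "params": self.params,
            "params_mb": self.params_mb,
            "model_size_mb": self.model_size_mb,
            "gflops": self.gflops,
        }


def count_macs(model: PoseModel, input_size: int) -> int:
    """Closed-form conv MAC count for one image at ``input_size``."""
    if input_size % model.max_stride:
        raise ValueError(f"input size must be divisible by {model.max_stride}")
    was_training = model.training
    model.eval()
    _conv.MAC_TRACE = []
    try:
        x = np.zeros((1, 3, _TRACE_SIZE, _TRACE_SIZE), dtype=np.float32)
        model.forward(x)
        macs_small = sum(_conv.MAC_TRACE)
    finally:
        _conv.MAC_TRACE = None
        model.train(was_training)
    scale = (input_size // model.max_stride) ** 2 / (_TRACE_SIZE // model.max_stride) ** 2
    return int(round(macs_small * scale))


def complexity(model: PoseModel, input_size: int | None = None) -> ComplexityReport:
    """Report parameter storage and GFLOPs for a built model."""
    if input_size is None:
        input_size = model.cfg.resolved_input_size()
    n_params = model.num_params()
    macs = count_macs(model, input_size)
    return ComplexityReport(
        params=n_params,
        params_mb=n_params * 4 / 2**20,
        model_size_mb=n_params * 2 / 2**20,
        gflops=macs * 2 / 1e9,
    )


def preset_complexity(preset: str, scale: str = "nano", input_size: int | None = None, seed: int = 0) -> ComplexityReport:
    cfg = ModelConfig.preset(preset, scale=scale)
    return complexity(build_model(cfg, seed=seed), input_size=input_size)
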