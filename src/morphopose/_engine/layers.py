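"""Neural-network layers on top of the autodiff tape.

Initialisation is Kaiming-uniform with an explicit ``numpy`` Generator so a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .conv import conv2d, global_avg_pool, max_pool2d, upsample_nearest2  # noqa: F401
from .tensor import Tensor


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Tiny nn.Module analogue: parameter discovery, train/eval, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and not value.requires_grad and name.startswith("running_"):
                yield prefix + name, value
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.data.copy() for k, v in self._named_buffers()})
        return state

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        own.update(dict(self._named_buffers()))
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict is missing {sorted(missing)[:5]}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=t.data.dtype)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        if p is None:
            p = k // 2
        self.stride, self.padding, self.groups = s, p, g
        rng = rng or np.random.default_rng(0)
        fan_in = c1 // g * k * k
        self.weight = Tensor(kaiming_uniform(rng, (c2, c1 // g, k, k), fan_in, dtype), requires_grad=True)
        if bias:
            bound = 1.0 / math.sqrt(fan_in) if fan_in else 0.0
            self.bias = Tensor(rng.uniform(-bound, bound, size=c2).astype(dtype), requires_grad=True)
        else:
            self.bias = None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)
        self.running_mean = Tensor(np.zeros(c, dtype=dtype))
        self.running_var = Tensor(np.ones(c, dtype=dtype))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean.data = (
                (1 - self.momentum) * self.running_mean.data + self.momentum * mean.data.ravel()
            )
            self.running_var.data = (
                (1 - self.momentum) * self.running_var.data + self.momentum * var.data.ravel()
            )
        else:
            mean = Tensor(self.running_mean.data.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, -1, 1, 1))
        xhat = (x - mean) / T.sqrt(var + self.eps)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, c1, c2, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(kaiming_uniform(rng, (c1, c2), c1, dtype), requires_grad=True)
        if bias:
            bound = 1.0 / math.sqrt(c1)
            self.bias = Tensor(rng.uniform(-bound, bound, size=c2).astype(dtype), requires_grad=True)
        else:
            self.bias = None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(d, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(d, dtype=dtype), requires_grad=True)

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / T.sqrt(var + self.eps) * self.weight + self.bias


class Dropout(Module):
    """Inverted dropout driven by a module-held Generator (seeded per model)."""

    def __init__(self, p=0.0, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTMCell(Module):
    def __init__(self, d_in, d_hidden, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_hidden = d_hidden
        self.w_ih = Linear(d_in, 4 * d_hidden, rng=rng, dtype=dtype)
        self.w_hh = Linear(d_hidden, 4 * d_hidden, bias=False, rng=rng, dtype=dtype)

    def forward(self, x, h, c):
        z = self.w_ih(x) + self.w_hh(h)
        d = self.d_hidden
        i = T.sigmoid(z[:, 0 * d : 1 * d])
        f = T.sigmoid(z[:, 1 * d : 2 * d])
        g = T.tanh(z[:, 2 * d : 3 * d])
        o = T.sigmoid(z[:, 3 * d : 4 * d])
        c_new = f * c + i * g
        h_new = o * T.tanh(c_new)
        return h_new, c_new
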