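"""Measurement regression from distance-feature vectors.

The core model is a Transformer encoder over *per-feature tokens*: each
scalar distance is embedded with a learned per-dimension value weight plus a
learned identity encoding, so multi-head self-attention can model global
geometric relationships among the keypoint distances.  Scaled dot-product
attention is the standard

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V.

Alternative architectures trained under the same protocol (MSE loss, Adam,
early stopping on validation loss): a Transformer with additional residual
skips around the encoder sublayers, a DeepMLP, a stacked LSTM that consumes
the tokens in the fixed anatomical order (the order is a convention, not a
true temporal sequence), and a 1-D CNN.

Targets are z-scored during training so the five measurements, whose
magnitudes differ by an order of magnitude, contribute comparably to the
loss; predictions are mapped back to centimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._engine import Adam, Dropout, LayerNorm, Linear, LSTMCell, Module, Tensor, T
from .core import MEASUREMENT_FIELDS, MeasurementRecord

ARCHITECTURES = ("transformer", "transformer_residual", "deep_mlp", "stacked_lstm", "cnn1d")


def attention(Q, K, V, dk: float):
    """Scaled dot-product attention on arrays or tape tensors.

    Rows of ``softmax(Q K^T / sqrt(dk))`` are convex weights over the value
    rows; shapes follow the usual (..., n_q, d) x (..., n_k, d) convention.
    """
    if dk <= 0:
        raise ValueError("dk must be positive")
    is_array = not isinstance(Q, Tensor)
    if is_array:
        Q, K, V = (Tensor(np.asarray(a, dtype=float)) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError(f"incompatible shapes {Q.shape}, {K.shape}, {V.shape}")
    scores = (Q @ K.transpose(*range(Q.ndim - 2), Q.ndim - 1, Q.ndim - 2)) * (1.0 / math.sqrt(dk))
    out = T.softmax(scores, axis=-1) @ V
    return out.data if is_array else out


@dataclass
class RegressorConfig:
    architecture: str = "transformer"
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    ffn_width: int = 128
    dropout: float = 0.1
    output_dim: int = len(MEASUREMENT_FIELDS)

    def validate(self) -> "RegressorConfig":
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        return self

    @property
    def dk(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class TrainProtocol:
    """Shared training protocol: MSE + Adam + early stopping."""

    lr: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    patience: int = 50
    max_epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> "TrainProtocol":
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        return self


class _MultiHeadSelfAttention(Module):
    def __init__(self, d_model, n_heads, rng):
        super().__init__()
        self.h, self.dk = n_heads, d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng=rng)
        self.proj = Linear(d_model, d_model, rng=rng)

    def forward(self, x):  # (B, F, d)
        b, f, d = x.shape
        qkv = self.qkv(x).reshape(b, f, 3, self.h, self.dk).transpose(2, 0, 3, 1, 4)
        out = attention(qkv[0], qkv[1], qkv[2], self.dk)  # (B, h, F, dk)
        return self.proj(out.transpose(0, 2, 1, 3).reshape(b, f, d))


class _EncoderBlock(Module):
    def __init__(self, cfg: RegressorConfig, rng, extra_residual: bool):
        super().__init__()
        self.attn = _MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn1 = Linear(cfg.d_model, cfg.ffn_width, rng=rng)
        self.ffn2 = Linear(cfg.ffn_width, cfg.d_model, rng=rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.extra_residual = extra_residual

    def forward(self, x):
        # canonical post-norm encoder sublayers; the residual variant adds an
        # extra identity skip around the whole block
        y = self.ln1(x + self.drop(self.attn(x)))
        y = self.ln2(y + self.drop(self.ffn2(T.relu(self.ffn1(y)))))
        return x + y if self.extra_residual else y


class _TransformerNet(Module):
    """Per-feature tokens -> encoder stack -> mean-pool -> dense decoder."""

    def __init__(self, cfg: RegressorConfig, input_dim: int, rng, residual: bool):
        super().__init__()
        self.value_w = Tensor(rng.normal(0, 0.5, (input_dim, cfg.d_model)).astype(np.float32), requires_grad=True)
        self.token_id = Tensor(rng.normal(0, 0.5, (input_dim, cfg.d_model)).astype(np.float32), requires_grad=True)
        self.blocks = [_EncoderBlock(cfg, rng, residual) for _ in range(cfg.n_layers)]
        self.ln = LayerNorm(cfg.d_model)
        # decoder sees the pooled encoding concatenated with the raw feature
        # vector, so linear structure has a direct dense path
        self.head = Linear(cfg.d_model + input_dim, cfg.output_dim, rng=rng)

    def forward(self, x):  # (B, F)
        tokens = x.reshape(x.shape[0], x.shape[1], 1) * self.value_w + self.token_id
        for blk in self.blocks:
            tokens = blk(tokens)
        pooled = self.ln(tokens).mean(axis=1)
        return self.head(T.concat([pooled, x], axis=1))


class _DeepMLPNet(Module):
    def __init__(self, cfg: RegressorConfig, input_dim: int, rng):
        super().__init__()
        widths = [input_dim, cfg.ffn_width, cfg.ffn_width, cfg.d_model]
        self.layers = [Linear(a, b, rng=rng) for a, b in zip(widths[:-1], widths[1:])]
        self.head = Linear(cfg.d_model, cfg.output_dim, rng=rng)

    def forward(self, x):
        for lin in self.layers:
            x = T.relu(lin(x))
        return self.head(x)


class _StackedLSTMNet(Module):
    """Tokens consumed in the fixed anatomical feature order."""

    def __init__(self, cfg: RegressorConfig, input_dim: int, rng):
        super().__init__()
        self.input_dim = input_dim
        self.token_id = Tensor(rng.normal(0, 0.5, (input_dim, cfg.d_model - 1)).astype(np.float32), requires_grad=True)
        self.cell1 = LSTMCell(cfg.d_model, cfg.d_model, rng=rng)
        self.cell2 = LSTMCell(cfg.d_model, cfg.d_model, rng=rng)
        self.head = Linear(cfg.d_model, cfg.output_dim, rng=rng)
        self.d = cfg.d_model

    def forward(self, x):  # (B, F)
        b = x.shape[0]
        h1 = c1 = h2 = c2 = Tensor(np.zeros((b, self.d), dtype=np.float32))
        for i in range(self.input_dim):
            ids = self.token_id[i : i + 1].reshape(1, self.d - 1) + Tensor(np.zeros((b, self.d - 1), dtype=np.float32))
            step = T.concat([x[:, i : i + 1], ids], axis=1)
            h1, c1 = self.cell1(step, h1, c1)
            h2, c2 = self.cell2(h1, h2, c2)
        return self.head(h2)


class _CNN1DNet(Module):
    """1-D convolutions over the ordered feature sequence (via 1xk kernels)."""

    def __init__(self, cfg: RegressorConfig, input_dim: int, rng):
        super().__init__()
        from ._engine import Conv2d

        self.conv1 = Conv2d(1, 32, 3, 1, None, rng=rng)
        self.conv2 = Conv2d(32, cfg.d_model, 3, 1, None, rng=rng)
        self.head = Linear(cfg.d_model, cfg.output_dim, rng=rng)

    def forward(self, x):  # (B, F)
        b, f = x.shape
        y = x.reshape(b, 1, 1, f)
        y = T.relu(self.conv1(y))
        y = T.relu(self.conv2(y))
        return self.head(y.mean(axis=3).reshape(b, -1))


def build_regressor(cfg: RegressorConfig, input_dim: int, seed: int = 0) -> Module:
    """Instantiate the network for ``cfg``; deterministic under the seed."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    if cfg.architecture == "transformer":
        return _TransformerNet(cfg, input_dim, rng, residual=False)
    if cfg.architecture == "transformer_residual":
        return _TransformerNet(cfg, input_dim, rng, residual=True)
    if cfg.architecture == "deep_mlp":
        return _DeepMLPNet(cfg, input_dim, rng)
    if cfg.architecture == "stacked_lstm":
        return _StackedLSTMNet(cfg, input_dim, rng)
    return _CNN1DNet(cfg, input_dim, rng)


class MeasurementRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style estimator mapping feature vectors to the five measures.

    Parameters mirror :class:`RegressorConfig` and :class:`TrainProtocol`;
    fitted state lives in trailing-underscore attributes.  ``fit`` accepts an
    explicit validation split (``X_val``, ``y_val``); otherwise a seeded
    fraction of the training rows is held out for early stopping.
    """

    def __init__(self, architecture="transformer", d_model=64, n_heads=4, n_layers=2,
                 ffn_width=128, dropout=0.1, lr=1e-2, patience=50, max_epochs=300,
                 batch_size=32, val_fraction=0.2, weight_decay=0.0, noise_sigma=0.0,
                 seed=0):
        self.architecture = architecture
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ffn_width = ffn_width
        self.dropout = dropout
        self.lr = lr
        self.patience = patience
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.weight_decay = weight_decay
        self.noise_sigma = noise_sigma
        self.seed = seed

    def _config(self) -> RegressorConfig:
        return RegressorConfig(
            architecture=self.architecture, d_model=self.d_model, n_heads=self.n_heads,
            n_layers=self.n_layers, ffn_width=self.ffn_width, dropout=self.dropout,
        ).validate()

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 2 or y.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, F) and y (n, 5) with matching n")
        protocol = TrainProtocol(
            lr=self.lr, patience=self.patience, max_epochs=self.max_epochs,
            batch_size=self.batch_size, seed=self.seed,
        ).validate()
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(len(X) * self.val_fraction)))
            if n_val >= len(X):
                raise ValueError("validation split would consume the whole training set")
            perm = rng.permutation(len(X))
            X, X_val = X[perm[n_val:]], X[perm[:n_val]]
            y, y_val = y[perm[n_val:]], y[perm[:n_val]]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float32)
            if len(X_val) == 0:
                raise ValueError("validation split is empty")

        # feature scaling + target z-scoring (frozen on the training rows)
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean_ = y.mean(axis=0)
        self.y_scale_ = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
        Xs, ys = (X - self.x_mean_) / self.x_scale_, (y - self.y_mean_) / self.y_scale_
        Xv, yv = (X_val - self.x_mean_) / self.x_scale_, (y_val - self.y_mean_) / self.y_scale_

        sigma_norm = None
        if np.any(np.asarray(self.noise_sigma) > 0):
            # noise_sigma is given in raw feature units (e.g. cm)
            sigma_norm = (np.asarray(self.noise_sigma, dtype=np.float32) / self.x_scale_).reshape(1, -1) \
                if np.ndim(self.noise_sigma) else np.float32(self.noise_sigma) / self.x_scale_
        self.model_ = build_regressor(self._config(), X.shape[1], seed=self.seed)
        opt = Adam(self.model_.parameters(), lr=protocol.lr, betas=protocol.betas,
                   weight_decay=self.weight_decay)
        best = (np.inf, None, -1)
        history = {"train_mse": [], "val_mse": []}
        bad = 0
        for epoch in range(protocol.max_epochs):
            # cosine decay to 1% of the base rate over the epoch budget
            opt.lr = protocol.lr * (0.01 + 0.99 * 0.5 * (1 + math.cos(math.pi * epoch / protocol.max_epochs)))
            self.model_.train()
            order = rng.permutation(len(Xs))
            losses = []
            for lo in range(0, len(order), protocol.batch_size):
                idx = order[lo : lo + protocol.batch_size]
                xb = Xs[idx]
                if sigma_norm is not None:
                    # train-time jitter matched to expected input noise
                    xb = xb + (rng.normal(0.0, 1.0, xb.shape) * sigma_norm).astype(np.float32)
                pred = self.model_(Tensor(xb))
                loss = ((pred - Tensor(ys[idx])) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.model_.eval()
            val_mse = float(np.mean((self.model_(Tensor(Xv)).data - yv) ** 2))
            history["train_mse"].append(float(np.mean(losses)))
            history["val_mse"].append(val_mse)
            if val_mse < best[0] - 1e-12:
                best = (val_mse, self.model_.state_dict(), epoch)
                bad = 0
            else:
                bad += 1
                if bad >= protocol.patience:
                    break
        if best[1] is not None:
            self.model_.load_state_dict(best[1])
        self.best_epoch_ = best[2]
        self.best_val_mse_ = best[0]
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        self.model_.eval()
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n, {self.n_features_in_}) features, got {X.shape}")
        Xs = (X - self.x_mean_) / self.x_scale_
        out = self.model_(Tensor(Xs)).data
        return out * self.y_scale_ + self.y_mean_

    def predict_records(self, X, individual_ids=None) -> list[MeasurementRecord]:
        preds = self.predict(X)
        ids = individual_ids if individual_ids is not None else [""] * len(preds)
        return [MeasurementRecord.from_array(p, individual_id=i) for p, i in zip(preds, ids)]


def train_regressor(model_or_arch, X, y, X_val=None, y_val=None, protocol: TrainProtocol | None = None,
                    **kwargs) -> MeasurementRegressor:
    """Functional wrapper over :class:`MeasurementRegressor`."""
    protocol = (protocol or TrainProtocol()).validate()
    arch = model_or_arch if isinstance(model_or_arch, str) else "transformer"
    est = MeasurementRegressor(
        architecture=arch, lr=protocol.lr, patience=protocol.patience,
        max_epochs=protocol.max_epochs, batch_size=protocol.batch_size, seed=protocol.seed,
        **kwargs,
    )
    return est.fit(X, y, X_val=X_val, y_val=y_val)


def predict_measurements(est: MeasurementRegressor, X, individual_ids=None) -> list[MeasurementRecord]:
    return est.predict_records(X, individual_ids)
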