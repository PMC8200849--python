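"""Convolutional-recurrent ON/OFF classifier.

Architecture: a temporal 1-D convolution over the spectrogram (per-channel
z-scored, 571 time steps x 201 frequency bins; the stated (4, 4) stride is
realized as stride 4 in time plus a 4x mean-decimation of the frequency axis
before the convolution) -> two stacked bidirectional recurrent layers (GRU or
LSTM, 128 units each), each followed by dropout and batch normalization -> a
per-timestep single-unit sigmoid head. With kernel 15 and temporal stride 4
the 571 input steps map to m = floor((571 - 15)/4) + 1 = 140 output steps.

Training minimizes per-timestep binary cross-entropy (targets 0 = OFF,
1 = ON repeated over the m steps) with the Adam optimizer. A segment-level
call binarizes the m sigmoid outputs at a threshold (the fixed reference
value is 0.44; a validation grid search is also provided) and declares ON iff more
than m/2 steps are ON.

The network — forward pass, backpropagation (including backprop through time
for both recurrent cell types and through batch normalization), and Adam —
is implemented directly on numpy arrays, batched over segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, LeakageError, TrainingDivergedError
from .features import chunk_training_audio

REFERENCE_THRESHOLD = 0.44


@dataclass
class CrnnConfig:
    """Hyperparameters. Defaults are the full-size architecture."""

    conv_filters: int = 196
    kernel_size: int = 15
    stride_time: int = 4
    stride_freq: int = 4
    recurrent_units: int = 128
    recurrent_kind: str = "gru"  # "gru" | "lstm"
    dropout_rate: float = 0.8
    threshold: float = REFERENCE_THRESHOLD
    threshold_mode: str = "fixed"  # "fixed" | "grid"
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    freq_mode: str = "decimate"  # "decimate" | "temporal"
    dtype: str = "float32"  # computation precision ("float64" for grad checks)

    def validate(self) -> None:
        if min(self.conv_filters, self.kernel_size, self.stride_time,
               self.recurrent_units, self.epochs, self.batch_size) <= 0:
            raise ConfigurationError("all size/count parameters must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.recurrent_kind not in ("gru", "lstm"):
            raise ConfigurationError("recurrent_kind must be 'gru' or 'lstm'")

    @classmethod
    def small(cls, **kw) -> "CrnnConfig":
        """Reduced architecture for desk-scale experiments: same layer
        topology, fewer filters/units/epochs and lighter dropout so that a
        leave-one-patient-out sweep runs in CPU minutes."""
        kw.setdefault("conv_filters", 12)
        kw.setdefault("recurrent_units", 6)
        kw.setdefault("dropout_rate", 0.2)
        kw.setdefault("epochs", 8)
        kw.setdefault("batch_size", 64)
        kw.setdefault("learning_rate", 3e-3)
        kw.setdefault("threshold_mode", "grid")
        return cls(**kw)


def output_steps(cfg: CrnnConfig, n_input_steps: int = 571) -> int:
    """Convolution length arithmetic: m = floor((n - kernel)/stride) + 1."""
    return (n_input_steps - cfg.kernel_size) // cfg.stride_time + 1


# ---------------------------------------------------------------------------
# Layers (forward + backward on (batch, time, features) arrays)
# ---------------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]


class FreqDecimate(_Layer):
    """Mean-pool the frequency axis with kernel = stride (non-overlapping)."""

    def __init__(self, stride: int):
        self.stride = stride
        self.params, self.grads = [], []

    def out_dim(self, d: int) -> int:
        return d // self.stride

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = self.out_dim(x.shape[2])
        self._in_dim = x.shape[2]
        return x[:, :, : d * self.stride].reshape(
            x.shape[0], x.shape[1], d, self.stride
        ).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t, d = dy.shape
        dx = np.zeros((b, t, self._in_dim), dtype=dy.dtype)
        dx[:, :, : d * self.stride] = np.repeat(dy / self.stride, self.stride, axis=2)
        return dx


class Conv1D(_Layer):
    """Temporal convolution (valid padding, configurable stride) + ReLU."""

    def __init__(self, in_dim: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (in_dim * kernel))
        self.W = rng.normal(0.0, scale, (kernel * in_dim, filters)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        bsz, t, d = x.shape
        m = (t - self.kernel) // self.stride + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = cols[:, :: self.stride][:, :m]          # (B, m, D, K)
        cols = np.ascontiguousarray(cols.swapaxes(2, 3))  # (B, m, K, D)
        self._cols = cols.reshape(bsz, m, self.kernel * d)
        self._in_shape = (bsz, t, d)
        z = self._cols @ self.W + self.b
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask
        bsz, m, f = dz.shape
        flat_cols = self._cols.reshape(bsz * m, -1)
        self.grads[0][...] = flat_cols.T @ dz.reshape(bsz * m, f)
        self.grads[1][...] = dz.sum(axis=(0, 1))
        dcol = dz @ self.W.T  # (B, m, K*D)
        _, t, d = self._in_shape
        dcol = dcol.reshape(bsz, m, self.kernel, d)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        steps = self.stride * np.arange(m)
        for k in range(self.kernel):
            dx[:, steps + k, :] += dcol[:, :, k, :]
        return dx


class _GRUCell:
    """Gates: z (update), r (reset); h' = (1 - z) h + z tanh(Wc x + Uc(r h))."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator, dtype=np.float32):
        h = units
        s_in = np.sqrt(1.0 / in_dim)
        s_h = np.sqrt(1.0 / h)
        self.W = rng.uniform(-s_in, s_in, (in_dim, 3 * h)).astype(dtype)
        self.U = rng.uniform(-s_h, s_h, (h, 3 * h)).astype(dtype)
        self.b = np.zeros(3 * h, dtype=dtype)
        self.units = h
        self.dtype = dtype
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, t, _ = x.shape
        h = self.units
        pre = x @ self.W + self.b  # (B, T, 3H)
        hs = np.zeros((bsz, t + 1, h), dtype=self.dtype)
        self._z = np.empty((bsz, t, h), dtype=self.dtype)
        self._r = np.empty((bsz, t, h), dtype=self.dtype)
        self._c = np.empty((bsz, t, h), dtype=self.dtype)
        Uzr, Uc = self.U[:, : 2 * h], self.U[:, 2 * h :]
        for i in range(t):
            hp = hs[:, i]
            zr = 1.0 / (1.0 + np.exp(-(pre[:, i, : 2 * h] + hp @ Uzr)))
            z, r = zr[:, :h], zr[:, h:]
            c = np.tanh(pre[:, i, 2 * h :] + (r * hp) @ Uc)
            hs[:, i + 1] = (1.0 - z) * hp + z * c
            self._z[:, i], self._r[:, i], self._c[:, i] = z, r, c
        self._x, self._hs = x, hs
        return hs[:, 1:]

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        bsz, t, _ = x.shape
        h = self.units
        Uzr, Uc = self.U[:, : 2 * h], self.U[:, 2 * h :]
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh = np.zeros((bsz, h), dtype=self.dtype)
        for i in range(t - 1, -1, -1):
            dh = dh + dh_out[:, i]
            z, r, c = self._z[:, i], self._r[:, i], self._c[:, i]
            hp = hs[:, i]
            dc = dh * z
            dz = dh * (c - hp)
            dhp = dh * (1.0 - z)
            dc_pre = dc * (1.0 - c * c)
            drh = dc_pre @ Uc.T
            dr = drh * hp
            dhp = dhp + drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dzr_pre = np.concatenate([dz_pre, dr_pre], axis=1)
            dpre = np.concatenate([dzr_pre, dc_pre], axis=1)
            dW += x[:, i].T @ dpre
            dU[:, : 2 * h] += hp.T @ dzr_pre
            dU[:, 2 * h :] += (r * hp).T @ dc_pre
            db += dpre.sum(axis=0)
            dx[:, i] = dpre @ self.W.T
            dhp = dhp + dzr_pre @ Uzr.T
            dh = dhp
        self.grads[0][...] = dW
        self.grads[1][...] = dU
        self.grads[2][...] = db
        return dx


class _LSTMCell:
    """Gates i, f, o and candidate g; c' = f c + i g; h = o tanh(c)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator, dtype=np.float32):
        h = units
        s_in = np.sqrt(1.0 / in_dim)
        s_h = np.sqrt(1.0 / h)
        self.W = rng.uniform(-s_in, s_in, (in_dim, 4 * h)).astype(dtype)
        self.U = rng.uniform(-s_h, s_h, (h, 4 * h)).astype(dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.units = h
        self.dtype = dtype
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, t, _ = x.shape
        h = self.units
        pre = x @ self.W + self.b
        hs = np.zeros((bsz, t + 1, h), dtype=self.dtype)
        cs = np.zeros((bsz, t + 1, h), dtype=self.dtype)
        self._g = np.empty((bsz, t, 4 * h), dtype=self.dtype)
        for i in range(t):
            a = pre[:, i] + hs[:, i] @ self.U
            ifo = 1.0 / (1.0 + np.exp(-a[:, : 3 * h]))
            g = np.tanh(a[:, 3 * h :])
            ig, fg, og = ifo[:, :h], ifo[:, h : 2 * h], ifo[:, 2 * h : 3 * h]
            cs[:, i + 1] = fg * cs[:, i] + ig * g
            hs[:, i + 1] = og * np.tanh(cs[:, i + 1])
            self._g[:, i] = np.concatenate([ifo, g], axis=1)
        self._x, self._hs, self._cs = x, hs, cs
        return hs[:, 1:]

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, hs, cs = self._x, self._hs, self._cs
        bsz, t, _ = x.shape
        h = self.units
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh = np.zeros((bsz, h), dtype=self.dtype)
        dc = np.zeros((bsz, h), dtype=self.dtype)
        for i in range(t - 1, -1, -1):
            dh = dh + dh_out[:, i]
            g4 = self._g[:, i]
            ig, fg, og, g = g4[:, :h], g4[:, h : 2 * h], g4[:, 2 * h : 3 * h], g4[:, 3 * h :]
            tc = np.tanh(cs[:, i + 1])
            do = dh * tc
            dc = dc + dh * og * (1.0 - tc * tc)
            di = dc * g
            df = dc * cs[:, i]
            dg = dc * ig
            dc_prev = dc * fg
            da = np.concatenate(
                [di * ig * (1 - ig), df * fg * (1 - fg), do * og * (1 - og),
                 dg * (1.0 - g * g)], axis=1)
            dW += x[:, i].T @ da
            dU += hs[:, i].T @ da
            db += da.sum(axis=0)
            dx[:, i] = da @ self.W.T
            dh = da @ self.U.T
            dc = dc_prev
        self.grads[0][...] = dW
        self.grads[1][...] = dU
        self.grads[2][...] = db
        return dx


class BiRNN(_Layer):
    """Bidirectional wrapper: concat(forward pass, time-reversed pass)."""

    def __init__(self, in_dim: int, units: int, kind: str, rng: np.random.Generator,
                 dtype=np.float32):
        cell = _GRUCell if kind == "gru" else _LSTMCell
        self.fwd = cell(in_dim, units, rng, dtype)
        self.bwd = cell(in_dim, units, rng, dtype)
        self.units = units
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.units
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :h]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, h:]))[:, ::-1]
        return dxf + dxb


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class BatchNorm(_Layer):
    """Per-feature normalization over the (batch, time) axes."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(dim, dtype=dtype)
        self.beta = np.zeros(dim, dtype=dtype)
        self.run_mean = np.zeros(dim, dtype=dtype)
        self.run_var = np.ones(dim, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0] * dy.shape[1]
        self.grads[0][...] = (dy * self._xhat).sum(axis=(0, 1))
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return self._istd * (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1))
        )


class TimeDense(_Layer):
    """Time-distributed single-unit head with sigmoid activation."""

    def __init__(self, in_dim: int, rng: np.random.Generator, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(1.0 / in_dim), (in_dim, 1)).astype(dtype)
        self.b = np.zeros(1, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        return 1.0 / (1.0 + np.exp(-z[..., 0]))

    def backward(self, dz: np.ndarray) -> np.ndarray:
        # dz is the gradient w.r.t. the pre-sigmoid logit (fused BCE+sigmoid)
        dz3 = dz[..., None]
        bsz, t, d = self._x.shape
        self.grads[0][...] = self._x.reshape(-1, d).T @ dz3.reshape(-1, 1)
        self.grads[1][...] = dz3.sum(axis=(0, 1))
        return dz3 @ self.W.T


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class CRNN:
    """The full network; see module docstring for the layer stack."""

    def __init__(self, cfg: CrnnConfig, input_shape: tuple[int, int] = (571, 201)):
        cfg.validate()
        self.cfg = cfg
        self.input_shape = input_shape
        n, f = input_shape
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        dtype = np.dtype(cfg.dtype).type
        self.dtype = dtype
        self.layers: list[_Layer] = []
        d = f
        if cfg.freq_mode == "decimate" and cfg.stride_freq > 1:
            dec = FreqDecimate(cfg.stride_freq)
            self.layers.append(dec)
            d = dec.out_dim(f)
        self.layers.append(
            Conv1D(d, cfg.conv_filters, cfg.kernel_size, cfg.stride_time, rng, dtype)
        )
        d = cfg.conv_filters
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        for _ in range(2):
            self.layers.append(BiRNN(d, cfg.recurrent_units, cfg.recurrent_kind, rng, dtype))
            d = 2 * cfg.recurrent_units
            self.layers.append(Dropout(cfg.dropout_rate, self._drop_rng))
            self.layers.append(BatchNorm(d, dtype=dtype))
        self.layers.append(TimeDense(d, rng, dtype))
        self.m = output_steps(cfg, n)

    @property
    def param_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1:] != self.input_shape:
            raise ContractError(
                f"expected input shape (batch, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}"
            )
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x  # (B, m) probabilities

    def backward(self, dz: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        return dz

    def predict(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [self.forward(x[i : i + batch], training=False) for i in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.empty((0, self.m))

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


def build_model(cfg: CrnnConfig, input_shape: tuple[int, int] = (571, 201)) -> CRNN:
    return CRNN(cfg, input_shape)


class _Adam:
    def __init__(self, model: CRNN, lr: float):
        self.pg = list(model.parameters())
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.lr, self.b1, self.b2, self.eps, self.t = lr, 0.9, 0.999, 1e-8, 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.pg):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train(
    model: CRNN,
    segments: np.ndarray,
    labels: np.ndarray,
    cfg: CrnnConfig | None = None,
) -> list[float]:
    """Fit the network with per-timestep BCE + Adam; returns per-epoch loss.

    ``segments``: (n, time, freq) normalized spectrogram stack (time-major);
    ``labels``: (n,) in {0, 1} (0 = OFF, 1 = ON), repeated over the m output
    steps as training targets.
    """
    cfg = cfg or model.cfg
    labels = np.asarray(labels, dtype=np.float64)
    if len(segments) != len(labels):
        raise ContractError("segments and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("training data must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    opt = _Adam(model, cfg.learning_rate)
    history: list[float] = []
    n = len(segments)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = segments[idx]
            y = labels[idx][:, None] * np.ones((1, model.m))
            p = model.forward(x, training=True).astype(np.float64)
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            model.backward(((p - y) / p.size).astype(model.dtype))
            opt.step()
            losses.append(loss * x.shape[0])
        history.append(float(np.sum(losses) / n))
    return history


# ---------------------------------------------------------------------------
# Decision rule and threshold selection
# ---------------------------------------------------------------------------


def decide(probs: np.ndarray, threshold: float = REFERENCE_THRESHOLD) -> str:
    """Binarize the m per-timestep outputs (prob >= threshold counts as ON)
    and call ON iff strictly more than m/2 steps are ON."""
    probs = np.asarray(probs)
    on_bits = int((probs >= threshold).sum())
    return "ON" if on_bits > probs.size / 2.0 else "OFF"


def decision_margin(probs: np.ndarray, threshold: float) -> float:
    """Signed vote margin (fraction of ON steps minus one half)."""
    probs = np.asarray(probs)
    return float((probs >= threshold).mean() - 0.5)


def select_threshold(
    folds: Sequence[Sequence[tuple[np.ndarray, str]]],
    mode: str = "grid",
    grid: np.ndarray | None = None,
) -> float:
    """Per-fold grid search for the validation-accuracy-maximizing threshold,
    averaged across folds. ``folds`` is a list of folds, each a list of
    (per-timestep probability vector, true label) validation pairs. Ties on
    the grid go to the smallest value. ``mode="fixed"`` returns the
    fixed reference value 0.44 regardless of data."""
    if mode == "fixed":
        return REFERENCE_THRESHOLD
    if not folds or not any(len(f) for f in folds):
        raise ConfigurationError("no validation predictions to select a threshold")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    per_fold = []
    for fold in folds:
        if not fold:
            continue
        best_t, best_acc = grid[0], -1.0
        for t in grid:
            acc = np.mean([decide(p, t) == truth for p, truth in fold])
            if acc > best_acc:
                best_t, best_acc = t, acc
        per_fold.append(best_t)
    return float(np.mean(per_fold))


# ---------------------------------------------------------------------------
# Training-set preparation
# ---------------------------------------------------------------------------


def prepare_training_set(
    manifest,
    audio16k: Mapping[tuple[int, str, str], np.ndarray],
    held_out_patient: int,
) -> list[tuple[np.ndarray, str]]:
    """Concatenate same-state training audio (manifest order, held-out
    patient excluded) and cut into labelled 10-s segments."""
    if manifest.empty:
        raise ConfigurationError("empty manifest")
    recs = []
    included: set[int] = set()
    for row in manifest.itertuples(index=False):
        if row.patient_id == held_out_patient:
            continue
        included.add(row.patient_id)
        key = (row.patient_id, row.protocol, row.state)
        recs.append((row.state, audio16k[key]))
    if held_out_patient in included:
        raise LeakageError("held-out patient present in training pool")
    states = {s for s, _ in recs}
    if states != {"ON", "OFF"}:
        raise ConfigurationError(f"training fold must contain both classes, has {states}")
    return chunk_training_audio(recs)
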