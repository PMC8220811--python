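"""CNN classifier over (1, G, K) expression-weight images, in pure numpy.

The architecture family: seven convolution blocks, each a 2-D convolution
followed by LeakyReLU (slope 0.1), then flatten, batch normalization, a
dense hidden layer with dropout, and a dense softmax output over the two
classes (non-metastasis, metastasis).  Training minimizes categorical
cross-entropy with the Adam optimizer.  The default block table shrinks the
long gene axis with stride-2 kernels while preserving the narrow cancer-type
axis.

Everything -- convolution via im2col, batch norm, dropout, backpropagation,
Adam -- is implemented here on numpy arrays, which keeps the classifier fully
deterministic under a seed: two runs with the same config and data produce
identical parameter trajectories.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .features import SampleFeatureTensor

logger = logging.getLogger(__name__)

_DTYPE = np.float32

DEFAULT_CONV_FILTERS = (8, 8, 16, 16, 32, 32, 64)
DEFAULT_CONV_KERNELS = ((7, 1), (7, 1), (5, 1), (5, 1), (3, 3), (3, 3), (3, 1))
DEFAULT_CONV_STRIDES = ((2, 1), (2, 1), (2, 1), (2, 1), (1, 1), (1, 1), (1, 1))

CLASS_ORDER = ("non_metastasis", "metastasis")  # positive class = column 1


@dataclass
class CNNConfig:
    """Hyperparameters of the CNN classifier.

    ``conv_filters``, ``conv_kernels`` and ``conv_strides`` must have equal
    length; seven blocks is the reference depth and any other length is
    accepted but logged as a deviation.  ``padding`` is "same" (default,
    stride-driven downsampling) or "valid".
    """

    conv_filters: tuple[int, ...] = DEFAULT_CONV_FILTERS
    conv_kernels: tuple[tuple[int, int], ...] = DEFAULT_CONV_KERNELS
    conv_strides: tuple[tuple[int, int], ...] = DEFAULT_CONV_STRIDES
    padding: str = "same"
    leaky_slope: float = 0.1
    dense_units: int = 64
    dropout_rate: float = 0.5
    n_classes: int = 2
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.conv_kernels = tuple(tuple(int(v) for v in k) for k in self.conv_kernels)
        self.conv_strides = tuple(tuple(int(v) for v in s) for s in self.conv_strides)
        if not (len(self.conv_filters) == len(self.conv_kernels) == len(self.conv_strides)):
            raise ConfigurationError(
                "conv_filters, conv_kernels and conv_strides must have equal length"
            )
        if len(self.conv_filters) != 7:
            logger.warning(
                "using %d conv blocks instead of the reference 7", len(self.conv_filters)
            )
        if self.leaky_slope <= 0:
            raise ConfigurationError("leaky_slope must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.padding not in ("same", "valid"):
            raise ConfigurationError(f"unknown padding {self.padding!r}")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.loss != "categorical_crossentropy":
            raise ConfigurationError("only categorical_crossentropy loss is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_kernels"] = [list(k) for k in self.conv_kernels]
        d["conv_strides"] = [list(s) for s in self.conv_strides]
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CNNConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def buffers(self) -> list[np.ndarray]:
        return []


def _same_padding(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(_Layer):
    """2-D convolution via im2col; NCHW layout."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        padding: str,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        scale = math.sqrt(2.0 / fan_in)  # He init, suits leaky-relu blocks
        self.weight = (rng.standard_normal((out_channels, fan_in)) * scale).astype(_DTYPE)
        self.bias = np.zeros(out_channels, dtype=_DTYPE)
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        if kh > h or kw > w:
            raise ConfigurationError(
                f"kernel {self.kernel} exceeds input spatial extent ({h}, {w})"
            )
        if self.padding == "same":
            return -(-h // sh), -(-w // sw)
        return (h - kh) // sh + 1, (w - kw) // sw + 1

    def _pads(self, h: int, w: int) -> tuple[tuple[int, int], tuple[int, int]]:
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.padding == "same":
            _, pt, pb = _same_padding(h, kh, sh)
            _, pl, pr = _same_padding(w, kw, sw)
            return (pt, pb), (pl, pr)
        return (0, 0), (0, 0)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        oh, ow = self.output_shape(h, w)
        (pt, pb), (pl, pr) = self._pads(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        windows = windows[:, :, ::sh, ::sw]  # (n, c, oh, ow, kh, kw)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, oh * ow, c * kh * kw
        )
        out = cols @ self.weight.T + self.bias
        self._cache = (cols, x.shape, (oh, ow), (pt, pb, pl, pr))
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, -1, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (oh, ow), (pt, pb, pl, pr) = self._cache
        n, c, h, w = x_shape
        kh, kw = self.kernel
        sh, sw = self.stride
        d2 = np.ascontiguousarray(dout.reshape(n, -1, oh * ow).transpose(0, 2, 1))
        self.grads[0][...] = np.einsum("npf,npk->fk", d2, cols, optimize=True)
        self.grads[1][...] = d2.sum(axis=(0, 1))
        dcols = (d2 @ self.weight).reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, pt : pt + h, pl : pl + w]


class LeakyReLU(_Layer):
    def __init__(self, slope: float) -> None:
        super().__init__()
        self.slope = float(slope)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class BatchNorm(_Layer):
    """Batch normalization over a flattened feature vector."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(dim, dtype=_DTYPE)
        self.beta = np.zeros(dim, dtype=_DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(dim, dtype=_DTYPE)
        self.running_var = np.ones(dim, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        self._cache = (xhat, ivar)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        n = dout.shape[0]
        self.grads[0][...] = (dout * xhat).sum(axis=0)
        self.grads[1][...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return ivar / n * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class Dense(_Layer):
    def __init__(self, dim_in: int, dim_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / dim_in)
        self.weight = (rng.standard_normal((dim_in, dim_out)) * scale).astype(_DTYPE)
        self.bias = np.zeros(dim_out, dtype=_DTYPE)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.weight.T


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class CNNModel:
    layers: list[_Layer]
    config: CNNConfig
    input_shape: tuple[int, int, int]  # (1, G, K)
    shape_chain: list[tuple[int, int, int]]
    rng: np.random.Generator

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params)
            out.extend(layer.buffers())
        return out

    def set_state(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise InvalidInputError(
                f"state has {len(arrays)} arrays, model expects {len(own)}"
            )
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise InvalidInputError(
                    f"state array shape {src.shape} != expected {dst.shape}"
                )
            dst[...] = src


def build_model(config: CNNConfig, input_shape: tuple[int, int, int]) -> CNNModel:
    """Assemble the CNN and validate the spatial shape chain.

    ``input_shape`` is ``(1, G, K)``.  A shape-inference pass runs the block
    table over the input extent; a kernel exceeding the running spatial size
    raises a :class:`ConfigurationError` naming the offending block.
    """
    if len(input_shape) != 3 or input_shape[0] != 1:
        raise ConfigurationError(f"input shape must be (1, G, K); got {input_shape}")
    rng = np.random.default_rng(config.seed)
    layers: list[_Layer] = []
    channels, (h, w) = 1, input_shape[1:]
    chain = [(channels, h, w)]
    for b, (filters, kernel, stride) in enumerate(
        zip(config.conv_filters, config.conv_kernels, config.conv_strides)
    ):
        conv = Conv2D(channels, filters, kernel, stride, config.padding, rng)
        try:
            h, w = conv.output_shape(h, w)
        except ConfigurationError as err:
            raise ConfigurationError(
                f"conv block {b + 1}: {err}; shape chain so far {chain}"
            ) from None
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"conv block {b + 1} collapses the spatial extent to ({h}, {w}); "
                f"shape chain so far {chain}"
            )
        channels = filters
        chain.append((channels, h, w))
        layers.append(conv)
        layers.append(LeakyReLU(config.leaky_slope))
    flat_dim = channels * h * w
    layers.append(Flatten())
    layers.append(BatchNorm(flat_dim))
    layers.append(Dense(flat_dim, config.dense_units, rng))
    layers.append(LeakyReLU(config.leaky_slope))
    layers.append(Dropout(config.dropout_rate, rng))
    layers.append(Dense(config.dense_units, config.n_classes, rng))
    logger.debug("shape chain: %s, flatten dim %d", chain, flat_dim)
    return CNNModel(
        layers=layers,
        config=config,
        input_shape=tuple(input_shape),
        shape_chain=chain,
        rng=rng,
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-(onehot * np.log(probs + eps)).sum() / probs.shape[0])


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A fitted CNN together with its training history and config snapshot."""

    model: CNNModel
    history: list[float]  # per-epoch mean training loss
    config: CNNConfig
    class_order: tuple[str, str] = CLASS_ORDER

    def save(self, path: str | Path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.model.state_arrays())}
        meta = json.dumps(
            {
                "config": self.config.to_dict(),
                "input_shape": list(self.model.input_shape),
                "history": self.history,
                "class_order": list(self.class_order),
            }
        )
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            n = len([k for k in data.files if k.startswith("arr_")])
            arrays = [data[f"arr_{i}"] for i in range(n)]
        config = CNNConfig.from_dict(meta["config"])
        model = build_model(config, tuple(meta["input_shape"]))
        model.set_state(arrays)
        return cls(
            model=model,
            history=list(meta["history"]),
            config=config,
            class_order=tuple(meta["class_order"]),
        )


def _as_tensor_array(features: SampleFeatureTensor | np.ndarray) -> np.ndarray:
    if isinstance(features, SampleFeatureTensor):
        x = features.values
    else:
        x = np.asarray(features)
    if x.ndim != 4:
        raise InvalidInputError(f"features must be rank-4 (m, 1, G, K); got {x.shape}")
    if x.size and not np.isfinite(x).all():
        raise InvalidInputError("features contain non-finite values")
    return x.astype(_DTYPE)


def train(
    model: CNNModel,
    features: SampleFeatureTensor | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    config: CNNConfig | None = None,
) -> TrainedModel:
    """Fit the CNN with Adam on categorical cross-entropy.

    Labels are 0/1 and one-hot encoded internally; a single-class vector is
    rejected because downstream ranking metrics would be undefined.  All
    randomness (shuffling, dropout) descends from ``config.seed``.
    """
    config = config or model.config
    x = _as_tensor_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if y.ndim != 1 or y.shape[0] != x.shape[0]:
        raise InvalidInputError(
            f"labels shape {y.shape} does not match {x.shape[0]} samples"
        )
    if np.unique(y).size < 2:
        raise InvalidInputError("labels contain a single class; training refused")
    if x.shape[1:] != model.input_shape:
        raise InvalidInputError(
            f"feature slices shaped {x.shape[1:]}, model expects {model.input_shape}"
        )
    onehot = np.zeros((y.shape[0], config.n_classes), dtype=_DTYPE)
    onehot[np.arange(y.shape[0]), y] = 1.0

    optimizer = _Adam(model.parameters(), config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed)
    m = x.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(m)
        total = 0.0
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            probs = _softmax(logits)
            total += _cross_entropy(probs, onehot[idx]) * idx.size
            model.backward((probs - onehot[idx]) / idx.size)
            optimizer.step(model.gradients())
        history.append(total / m)
    return TrainedModel(model=model, history=history, config=config)


def predict_proba(
    trained: TrainedModel,
    features: SampleFeatureTensor | np.ndarray,
    batch_size: int = 256,
) -> np.ndarray:
    """Class probabilities, rows summing to 1; column order = class_order."""
    x = _as_tensor_array(features)
    if x.shape[0] == 0:
        return np.zeros((0, trained.config.n_classes), dtype=np.float64)
    if x.shape[1:] != trained.model.input_shape:
        raise InvalidInputError(
            f"feature slices shaped {x.shape[1:]}, model expects "
            f"{trained.model.input_shape}"
        )
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        logits = trained.model.forward(x[start : start + batch_size], train=False)
        chunks.append(_softmax(logits))
    return np.concatenate(chunks).astype(np.float64)
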