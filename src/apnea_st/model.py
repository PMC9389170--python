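"""The trainable CNN-BiGRU-attention network for per-minute apnea detection.

The architecture is a stack of "spatio-temporal blocks" — 1-D convolution,
max pooling, dropout, bidirectional GRU — preceded by a stem convolution and
followed by dot-product attention over the last BiGRU's forward/backward
state stacks, a flatten, and three dense layers ending in a 2-way softmax.
Between blocks the forward and backward stacks are concatenated along the
channel dimension; only the final BiGRU feeds them to attention separately.

With the default geometry (900-point input, kernel 3, pool 3, three blocks)
the sequence length contracts 900 -> 300 -> 100 -> 33, so attention mixes 33
high-level time steps.

Layers run on the reverse-mode engine in :mod:`apnea_st.autodiff`; the
defining equations of each layer have independent oracle implementations in
:mod:`apnea_st.reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, ShapeError

__all__ = ["ModelSpec", "Model", "build_model", "model_forward"]


@dataclass
class ModelSpec:
    """Hyperparameters of the network; defaults are the full-size configuration."""

    n_blocks: int = 3
    filters: int = 128
    kernel_size: int = 3
    pool_size: int = 3
    gru_units: int = 128
    dense_units: int = 64
    dropout_rate: float = 0.2
    n_classes: int = 2
    input_len: int = 900
    input_channels: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if min(self.filters, self.kernel_size, self.pool_size, self.gru_units) < 1:
            raise ConfigError("filters, kernel_size, pool_size and gru_units must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")

    def tiny(self) -> "ModelSpec":
        """The small test-bed configuration: 1 block, 8 filters, 8 GRU units."""
        return ModelSpec(
            n_blocks=1, filters=8, gru_units=8, dense_units=16,
            dropout_rate=self.dropout_rate,
            input_len=self.input_len, input_channels=self.input_channels,
        )


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Layer:
    name = "layer"

    def params(self) -> list[Tensor]:
        return []

    def __call__(self, x, training: bool, rng) -> Tensor:
        raise NotImplementedError

    def describe(self) -> tuple[str, str, str, str]:
        """(type, units/filters, kernel, activation) for the printed layer table."""
        return (self.name, "-", "-", "-")


class _Conv(_Layer):
    name = "Convolutional"

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.w = Tensor(
            _glorot(rng, (kernel, cin, cout), kernel * cin, kernel * cout),
            requires_grad=True,
        )

    def params(self):
        return [self.w]

    def __call__(self, x, training, rng):
        return ad.relu(ad.conv1d_same(x, self.w))

    def describe(self):
        return (self.name, str(self.w.shape[2]), str(self.kernel), "ReLU")


class _MaxPool(_Layer):
    name = "Max-Pooling"

    def __init__(self, k: int):
        self.k = k

    def __call__(self, x, training, rng):
        return ad.max_pool1d(x, self.k)

    def describe(self):
        return (self.name, "-", str(self.k), "-")


class _Dropout(_Layer):
    name = "Dropout"

    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x, training, rng):
        if not training or self.rate <= 0:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class _BiGRU(_Layer):
    """Bidirectional GRU over (B, s, c); literal gate convention, no biases.

    Returns the concatenated (B, s, 2n) stack, or the (F, B) pair when
    ``return_pair`` — the form the attention layer consumes.
    """

    name = "Bidirectional GRU"

    def __init__(self, cin: int, units: int, rng: np.random.Generator, return_pair: bool = False):
        self.units = units
        self.return_pair = return_pair
        def w():
            return Tensor(_glorot(rng, (cin, units), cin, units), requires_grad=True)
        def u():
            return Tensor(_glorot(rng, (units, units), units, units), requires_grad=True)
        # per direction: W_r, U_r, W_z, U_z, W_x, U_x
        self.fwd = [w(), u(), w(), u(), w(), u()]
        self.bwd = [w(), u(), w(), u(), w(), u()]

    def params(self):
        return self.fwd + self.bwd

    def _run(self, x: Tensor, weights: list[Tensor], reverse: bool) -> Tensor:
        W_r, U_r, W_z, U_z, W_x, U_x = weights
        batch, s, _ = x.shape
        # project the whole sequence through the input weights once
        xr, xz, xc = x @ W_r, x @ W_z, x @ W_x
        h = Tensor(np.zeros((batch, self.units)))
        states = []
        steps = range(s - 1, -1, -1) if reverse else range(s)
        for t in steps:
            idx = (slice(None), t, slice(None))
            r = ad.sigmoid(xr[idx] + h @ U_r)
            z = ad.sigmoid(xz[idx] + h @ U_z)
            h_tilde = ad.tanh(xc[idx] + r * (h @ U_x))
            h = z * h + (1.0 - z) * h_tilde
            states.append(h)
        if reverse:
            states.reverse()
        return ad.stack(states, axis=1)  # (B, s, n), time-aligned

    def __call__(self, x, training, rng):
        F = self._run(x, self.fwd, reverse=False)
        B = self._run(x, self.bwd, reverse=True)
        if self.return_pair:
            return (F, B)
        return ad.concat([F, B], axis=-1)

    def describe(self):
        return (self.name, str(self.units), "-", "Tanh")


class _Attention(_Layer):
    name = "Attention"

    def __call__(self, fb, training, rng):
        F, B = fb
        scores = F @ B.swapaxes(1, 2)
        return ad.softmax(scores, axis=-1) @ B


class _Flatten(_Layer):
    name = "Flatten"

    def __call__(self, x, training, rng):
        return x.reshape(x.shape[0], -1)


class _Dense(_Layer):
    name = "Dense"

    def __init__(self, din: int, dout: int, activation: str, rng: np.random.Generator):
        self.activation = activation
        self.w = Tensor(_glorot(rng, (din, dout), din, dout), requires_grad=True)
        self.b = Tensor(np.zeros(dout), requires_grad=True)

    def params(self):
        return [self.w, self.b]

    def __call__(self, x, training, rng):
        y = x @ self.w + self.b
        if self.activation == "relu":
            return ad.relu(y)
        if self.activation == "softmax":
            return ad.softmax(y, axis=-1)
        return y

    def describe(self):
        act = {"relu": "ReLU", "softmax": "Softmax"}.get(self.activation, "-")
        return (self.name, str(self.w.shape[1]), "-", act)


@dataclass
class Model:
    """A built network: ordered layers plus the spec that produced them."""

    spec: ModelSpec
    layers: list = field(default_factory=list)
    seq_lengths: list = field(default_factory=list)

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]

    def num_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ShapeError(f"expected {len(params)} weight arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            w = np.asarray(w, dtype=float)
            if w.shape != p.data.shape:
                raise ShapeError(f"weight shape {w.shape} incompatible with {p.data.shape}")
            p.data = w.copy()

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Probability pairs (B, 2); dropout active only when ``training``."""
        x = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=float))
        if x.data.ndim != 3 or x.data.shape[1:] != (self.spec.input_len, self.spec.input_channels):
            raise ShapeError(
                f"expected input (batch, {self.spec.input_len}, {self.spec.input_channels}), "
                f"got {x.data.shape}"
            )
        if training and rng is None:
            rng = np.random.default_rng(0)
        for layer in self.layers:
            x = layer(x, training, rng)
        return x

    def layer_table(self) -> str:
        rows = [("Layer", "Type", "Filters/Units", "Kernel", "Activation")]
        for i, layer in enumerate(self.layers, start=1):
            t, units, kernel, act = layer.describe()
            rows.append((str(i), t, units, kernel, act))
        widths = [max(len(r[c]) for r in rows) for c in range(5)]
        return "\n".join(
            "  ".join(v.ljust(w) for v, w in zip(r, widths)) for r in rows
        )


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Assemble the layer stack for ``spec`` with seeded Glorot initialization.

    Raises :class:`ConfigError` if pooling would collapse the sequence length
    below 1 before the final block.
    """
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    seq_len = spec.input_len
    seq_lengths = [seq_len]
    cin = spec.input_channels

    layers.append(_Conv(cin, spec.filters, spec.kernel_size, rng))  # stem
    cin = spec.filters
    for b in range(spec.n_blocks):
        last = b == spec.n_blocks - 1
        layers.append(_Conv(cin, spec.filters, spec.kernel_size, rng))
        if seq_len < spec.pool_size:
            raise ConfigError(
                f"block {b + 1}: sequence length {seq_len} cannot be pooled by {spec.pool_size}"
            )
        seq_len //= spec.pool_size
        if seq_len < 1:
            raise ConfigError(f"block {b + 1}: sequence length collapsed below 1")
        seq_lengths.append(seq_len)
        layers.append(_MaxPool(spec.pool_size))
        layers.append(_Dropout(spec.dropout_rate))
        layers.append(_BiGRU(spec.filters, spec.gru_units, rng, return_pair=last))
        cin = 2 * spec.gru_units
        if not last:
            layers.append(_Dropout(spec.dropout_rate))
    layers.append(_Attention())
    layers.append(_Flatten())
    flat = seq_len * spec.gru_units
    layers.append(_Dense(flat, spec.dense_units, "relu", rng))
    layers.append(_Dropout(spec.dropout_rate))
    layers.append(_Dense(spec.dense_units, spec.dense_units, "relu", rng))
    layers.append(_Dense(spec.dense_units, spec.n_classes, "softmax", rng))
    return Model(spec=spec, layers=layers, seq_lengths=seq_lengths)


def model_forward(model: Model, X, batch_size: int = 256) -> np.ndarray:
    """Deterministic inference (dropout off): class probabilities (n, 2)."""
    X = np.asarray(X, dtype=float)
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.forward(X[i : i + batch_size], training=False).data)
    return np.concatenate(out, axis=0) if out else np.zeros((0, model.spec.n_classes))
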