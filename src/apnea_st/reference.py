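"""Reference implementations of the network's constituent operations.

These are direct, loop-level NumPy transcriptions of the defining equations
of each layer — 1-D convolution, max pooling, the GRU cell, the
bidirectional GRU, and dot-product attention.  They share no code with the
trainable network in :mod:`apnea_st.model` and exist so the two routes can
be checked against each other.

Conventions
-----------
* GRU cell (literal form, no bias terms)::

      r = sigmoid(W_r x + U_r h_prev)
      z = sigmoid(W_z x + U_z h_prev)
      h~ = tanh(W_x x + r * (U_x h_prev))
      h = z * h_prev + (1 - z) * h~

  Note the update gate multiplies the *previous* state; the mirrored
  convention (z on the candidate) is equivalent under z <-> 1-z.
* Dot-product attention: ``a = softmax(F B^T) B`` with the softmax taken
  row-wise over key positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError

__all__ = ["GRUCellParams", "BiGRUOutput", "conv1d", "max_pool", "gru_step", "bigru_run", "dot_attention"]


@dataclass
class GRUCellParams:
    """GRU cell weights: ``W_*`` are (n, input_dim), ``U_*`` are (n, n)."""

    W_r: np.ndarray
    U_r: np.ndarray
    W_z: np.ndarray
    U_z: np.ndarray
    W_x: np.ndarray
    U_x: np.ndarray

    def __post_init__(self) -> None:
        n, c = self.W_r.shape
        for name in ("W_z", "W_x"):
            if getattr(self, name).shape != (n, c):
                raise ShapeError(f"{name} must be ({n}, {c})")
        for name in ("U_r", "U_z", "U_x"):
            if getattr(self, name).shape != (n, n):
                raise ShapeError(f"{name} must be ({n}, {n})")

    @property
    def n(self) -> int:
        return self.W_r.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_r.shape[1]

    @classmethod
    def random(cls, input_dim: int, n: int, rng: np.random.Generator, scale: float = 0.5):
        m = lambda *s: rng.uniform(-scale, scale, size=s)
        return cls(m(n, input_dim), m(n, n), m(n, input_dim), m(n, n), m(n, input_dim), m(n, n))


@dataclass
class BiGRUOutput:
    """Time-aligned forward (F) and backward (B) hidden-state stacks, each (s, n)."""

    F: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        if self.F.shape != self.B.shape:
            raise ShapeError(f"F {self.F.shape} and B {self.B.shape} must match")


def conv1d(x: np.ndarray, w: np.ndarray, padding: str = "valid") -> np.ndarray:
    """Multi-channel cross-correlation ``y[i] = sum_u sum_c w[u,c,k] x[i+u,c]``.

    ``x`` may be (T,) or (T, C); ``w`` may be (L,), (L, C) for a single
    filter or (L, C, K) for a bank.  Returns a shape matching the input /
    filter-bank arrangement, with "same" padding splitting the L-1 zeros as
    evenly as possible (extra zero on the right).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    squeeze_ch = x.ndim == 1
    if squeeze_ch:
        x = x[:, None]
    if w.ndim == 1:
        w = w[:, None]
    squeeze_k = w.ndim == 2
    if squeeze_k:
        w = w[:, :, None]
    L, C, K = w.shape
    if C != x.shape[1]:
        raise ShapeError(f"input has {x.shape[1]} channels, filter expects {C}")
    if padding == "same":
        pad_l = (L - 1) // 2
        x = np.pad(x, ((pad_l, L - 1 - pad_l), (0, 0)))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    T = x.shape[0] - L + 1
    if T < 1:
        raise ShapeError(f"kernel length {L} exceeds padded input length {x.shape[0]}")
    out = np.zeros((T, K))
    for i in range(T):
        for u in range(L):
            out[i] += w[u].T @ x[i + u]
    if squeeze_k:
        out = out[:, 0]
    return out


def max_pool(x: np.ndarray, k: int = 3, stride: int = 3) -> np.ndarray:
    """Window maxima over the time axis; the trailing remainder (< k) is dropped."""
    if k < 1:
        raise ValueError(f"pool size must be >= 1, got {k}")
    x = np.asarray(x, dtype=float)
    if x.shape[0] < k:
        raise ShapeError(f"series of length {x.shape[0]} shorter than pool size {k}")
    starts = range(0, x.shape[0] - k + 1, stride)
    return np.stack([x[s : s + k].max(axis=0) for s in starts])


def gru_step(p: GRUCellParams, h_prev: np.ndarray, x_t: np.ndarray) -> np.ndarray:
    """One GRU update in the literal gate convention (see module docstring)."""
    h_prev = np.asarray(h_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if h_prev.shape != (p.n,) or x_t.shape != (p.input_dim,):
        raise ShapeError(
            f"expected h_prev ({p.n},) and x_t ({p.input_dim},), "
            f"got {h_prev.shape} and {x_t.shape}"
        )
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    r = sig(p.W_r @ x_t + p.U_r @ h_prev)
    z = sig(p.W_z @ x_t + p.U_z @ h_prev)
    h_tilde = np.tanh(p.W_x @ x_t + r * (p.U_x @ h_prev))
    return z * h_prev + (1 - z) * h_tilde


def bigru_run(p_fwd: GRUCellParams, p_bwd: GRUCellParams, seq: np.ndarray) -> BiGRUOutput:
    """Run both GRU directions from zero initial states over ``seq`` (s, c).

    ``F[t]`` is the forward state after consuming ``seq[0..t]``; ``B[t]`` the
    backward state after consuming ``seq[s-1..t]`` — i.e. B is re-reversed to
    input time order.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("seq must be a non-empty (s, c) array")
    s = seq.shape[0]
    F = np.zeros((s, p_fwd.n))
    h = np.zeros(p_fwd.n)
    for t in range(s):
        h = gru_step(p_fwd, h, seq[t])
        F[t] = h
    B = np.zeros((s, p_bwd.n))
    h = np.zeros(p_bwd.n)
    for t in range(s - 1, -1, -1):
        h = gru_step(p_bwd, h, seq[t])
        B[t] = h
    return BiGRUOutput(F=F, B=B)


def dot_attention(F: np.ndarray, B: np.ndarray) -> np.ndarray:
    """``a = softmax(F B^T) B`` with a row-wise softmax over key positions."""
    F = np.asarray(F, dtype=float)
    B = np.asarray(B, dtype=float)
    if F.shape != B.shape:
        raise ShapeError(f"F {F.shape} and B {B.shape} must have equal shape")
    scores = F @ B.T
    scores = scores - scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ B
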