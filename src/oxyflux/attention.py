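"""Temporal, spatial and spatio-temporal attention over C×W feature maps.

The representation is a matrix of C time steps by W feature dimensions
(image-style H×W spatial structure is absent in multivariate time series,
so only these two axes remain).

* TAM (temporal attention) is a squeeze-excitation gate over time steps:
  each time channel is squeezed to a scalar by averaging over the W
  features, passed through a bottleneck MLP (reduction ratio r, no biases)
  and a sigmoid, and the resulting per-step weight rescales its row.
* SAM (spatial attention) gates feature dimensions: average- and
  max-pooling over the time axis give two 1×W descriptors, which a shared
  same-padded 1-D convolution maps to per-feature logits; the sigmoid map
  rescales columns.
* STAM cascades the two (default SAM then TAM; order is configurable).

Because every weight is a sigmoid output, attention strictly shrinks
magnitudes: all weights lie in the open interval (0, 1).

Each operator exists in two forms: a Tensor-level function used inside the
networks (batched, differentiable) and a plain-numpy wrapper returning the
reweighted map together with its attention weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, conv1d_same


@dataclass(frozen=True)
class SEParams:
    """Squeeze-excitation bottleneck weights: W1 (C/r × C), W2 (C × C/r)."""

    W1: np.ndarray
    W2: np.ndarray
    r: int

    def __post_init__(self):
        c = self.W1.shape[1]
        if self.r < 1 or c % self.r != 0:
            raise ValueError("reduction ratio r must divide C")
        if self.W1.shape != (c // self.r, c) or self.W2.shape != (c, c // self.r):
            raise ValueError("W1/W2 shapes inconsistent with C and r")

    @classmethod
    def zeros(cls, c: int, r: int = 2) -> "SEParams":
        return cls(W1=np.zeros((c // r, c)), W2=np.zeros((c, c // r)), r=r)


@dataclass(frozen=True)
class AttentionWeights:
    kind: str              # "temporal" | "spatial"
    values: np.ndarray     # length C (temporal) or W (spatial), in (0, 1)


# ---------------------------------------------------------------------------
# Tensor-level (batched, differentiable) operators used by the models.

def tam_forward(f: Tensor, w1: Tensor, w2: Tensor) -> tuple[Tensor, Tensor]:
    """Squeeze-excitation over time steps. f: (N, C, W) → (f', S (N, C))."""
    n, c, _ = f.shape
    z = f.mean(axis=2)                               # squeeze: (N, C)
    hidden = (z @ w1.T).relu()
    s = (hidden @ w2.T).sigmoid()                    # (N, C)
    out = f * s.reshape(n, c, 1)
    return out, s


def sam_forward(f: Tensor, conv_w: Tensor, conv_b: Tensor) -> tuple[Tensor, Tensor]:
    """CBAM-style spatial gate. f: (N, C, W) → (f', M (N, W))."""
    n, _, w = f.shape
    avg = f.mean(axis=1).reshape(n, 1, w)
    mx = f.max(axis=1).reshape(n, 1, w)
    stacked = concat([avg, mx], axis=1)              # (N, 2, W)
    logits = conv1d_same(stacked, conv_w, conv_b)    # (N, 1, W)
    m = logits.sigmoid()
    out = f * m
    return out, m.reshape(n, w)


def stam_forward(f: Tensor, conv_w: Tensor, conv_b: Tensor,
                 w1: Tensor, w2: Tensor, order: str = "sam_first"):
    """Cascade of SAM and TAM. Returns (f', M_spatial, S_temporal)."""
    if order == "sam_first":
        f, m = sam_forward(f, conv_w, conv_b)
        f, s = tam_forward(f, w1, w2)
    elif order == "tam_first":
        f, s = tam_forward(f, w1, w2)
        f, m = sam_forward(f, conv_w, conv_b)
    else:
        raise ValueError("order must be 'sam_first' or 'tam_first'")
    return f, m, s


# ---------------------------------------------------------------------------
# Plain-numpy single-map wrappers.

def _check_map(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1 or f.shape[1] < 1:
        raise ValueError("feature map must be a C×W matrix")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map must be finite")
    return f


def tam_apply(f, params: SEParams) -> tuple[np.ndarray, AttentionWeights]:
    """Apply temporal (SE) attention to a single C×W map."""
    f = _check_map(f)
    c = f.shape[0]
    if params.W1.shape[1] != c:
        raise ValueError(f"SEParams built for C={params.W1.shape[1]}, map has C={c}")
    out, s = tam_forward(Tensor(f[None]), Tensor(params.W1), Tensor(params.W2))
    return out.data[0], AttentionWeights("temporal", s.data[0])


def sam_apply(f, kernel, bias: float = 0.0) -> tuple[np.ndarray, AttentionWeights]:
    """Apply spatial attention to a single C×W map.

    `kernel` is the 1-D convolution weight of shape (2, k) — one row per
    pooled descriptor (average, max) — with odd k ≤ W; `bias` is its scalar
    bias term.
    """
    f = _check_map(f)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] != 2:
        raise ValueError("kernel must have shape (2, k)")
    k = kernel.shape[1]
    if k % 2 == 0 or k > f.shape[1]:
        raise ValueError("kernel length must be odd and no longer than W")
    out, m = sam_forward(Tensor(f[None]), Tensor(kernel[None]),
                         Tensor(np.array([bias])))
    return out.data[0], AttentionWeights("spatial", m.data[0])


def stam_apply(f, kernel, tam_params: SEParams, bias: float = 0.0,
               order: str = "sam_first"):
    """Cascaded spatio-temporal attention on a single C×W map."""
    f = _check_map(f)
    kernel = np.asarray(kernel, dtype=float)
    out, m, s = stam_forward(Tensor(f[None]), Tensor(kernel[None]),
                             Tensor(np.array([bias])),
                             Tensor(tam_params.W1), Tensor(tam_params.W2),
                             order=order)
    return (out.data[0], AttentionWeights("spatial", m.data[0]),
            AttentionWeights("temporal", s.data[0]))
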