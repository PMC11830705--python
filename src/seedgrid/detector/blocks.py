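"""NumPy forward passes for the detector's attention building blocks.

Two blocks modify the baseline one-stage detector for seed imagery:

* **ECA** (efficient channel attention) — per-channel gating computed by a
  1-D convolution over the globally average-pooled channel vector, with no
  dimensionality reduction.  The kernel size adapts to the channel count.
* **ODConv** (omni-dimensional dynamic convolution) — a convolution whose
  effective kernel is an attention-weighted combination of ``n`` candidate
  kernels, with complementary attention along four axes: spatial position,
  input channel, output channel, and kernel index.

Feature tensors are channel-last ``(H, W, C)`` float arrays.  These are
inference-path implementations with explicit parameters; they double as
ground truth for the assembled network in :mod:`seedgrid.detector.model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError

__all__ = [
    "conv2d",
    "sigmoid",
    "eca_kernel_size",
    "eca_forward",
    "ECA",
    "OdconvAttention",
    "odconv_forward",
    "ODConv",
]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def conv2d(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    padding: str | int = "same",
) -> np.ndarray:
    """2-D cross-correlation of a channel-last tensor.

    ``x``: (H, W, C_in); ``weight``: (C_out, k, k, C_in).  ``padding`` is
    "same" (zero-pad to k//2) or an explicit integer.  Returns
    (H', W', C_out).
    """
    x = np.asarray(x, dtype=np.float32)
    weight = np.asarray(weight, dtype=np.float32)
    c_out, k, k2, c_in = weight.shape
    if k != k2:
        raise ConfigError("only square kernels supported")
    if x.ndim != 3 or x.shape[2] != c_in:
        raise ConfigError(
            f"input shape {x.shape} incompatible with kernel C_in={c_in}"
        )
    pad = k // 2 if padding == "same" else int(padding)
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    win = win[::stride, ::stride]  # (H', W', C_in, k, k)
    h, w = win.shape[:2]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * w, k * k * c_in)
    flat_w = weight.transpose(0, 1, 2, 3).reshape(c_out, k * k * c_in)
    out = cols @ flat_w.T
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float32)
    return out.reshape(h, w, c_out)


# --- ECA ---------------------------------------------------------------


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive odd 1-D kernel size: nearest odd to ``|log2(C)/gamma + b/gamma|``."""
    if channels < 1:
        raise ConfigError("channel count must be positive")
    t = int(abs(math.log2(channels) / gamma + b / gamma))
    return t if t % 2 else t + 1


def eca_forward(
    features: np.ndarray,
    conv_weights: np.ndarray | None = None,
    gamma: float = 2.0,
    b: float = 1.0,
) -> np.ndarray:
    """Efficient channel attention over a ``(H, W, C)`` tensor.

    Global average pooling squeezes the input to a length-``C`` vector; a
    1-D convolution of adaptive odd size ``k`` (zero-padded, no bias) mixes
    each channel with its ``k - 1`` neighbours; a sigmoid turns the result
    into per-channel weights in (0, 1) that rescale the input.  Shape is
    always preserved.

    ``conv_weights`` is the length-``k`` kernel; if omitted, a uniform
    ``1/k`` kernel is used.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] < 1:
        raise ConfigError("eca_forward expects a (H, W, C) tensor with C >= 1")
    c = x.shape[2]
    k = eca_kernel_size(c, gamma, b)
    if conv_weights is None:
        conv_weights = np.full(k, 1.0 / k)
    conv_weights = np.asarray(conv_weights, dtype=np.float64)
    if conv_weights.shape != (k,):
        raise ConfigError(f"conv_weights must have shape ({k},) for C={c}")
    gap = x.mean(axis=(0, 1))
    padded = np.pad(gap, (k // 2, k // 2))
    mixed = np.correlate(padded, conv_weights, mode="valid")
    weights = sigmoid(mixed)
    return x * weights[None, None, :]


class ECA:
    """Stateful ECA block holding its 1-D kernel weights."""

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0, rng=None):
        self.channels = channels
        self.gamma = gamma
        self.b = b
        self.k = eca_kernel_size(channels, gamma, b)
        rng = rng or np.random.default_rng(0)
        self.weights = rng.normal(0.0, 1.0 / self.k, size=self.k)

    @property
    def n_params(self) -> int:
        return self.k

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return eca_forward(x, self.weights, self.gamma, self.b)


# --- ODConv ------------------------------------------------------------


@dataclass(frozen=True)
class OdconvAttention:
    """The four complementary attention factors of one ODConv call.

    ``kernel`` (length n) lies on the probability simplex; ``spatial``
    (k x k), ``in_channel`` (C_in) and ``out_channel`` (C_out) are
    sigmoid-gated, i.e. elementwise in (0, 1] (exactly 1 is allowed so the
    identity attention is expressible).
    """

    kernel: np.ndarray
    spatial: np.ndarray
    in_channel: np.ndarray
    out_channel: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size < 1:
            raise ConfigError("kernel attention must be a 1-D vector")
        if not math.isclose(float(k.sum()), 1.0, abs_tol=1e-6):
            raise ConfigError("kernel attention must sum to 1 (simplex)")
        for name in ("spatial", "in_channel", "out_channel"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.size and (a.min() < 0 or a.max() > 1):
                raise ConfigError(f"{name} attention must lie in [0, 1]")

    @property
    def n_kernels(self) -> int:
        return len(self.kernel)


def combine_kernels(kernels: np.ndarray, attn: OdconvAttention) -> np.ndarray:
    """Attention-weighted sum of candidate kernels.

    ``kernels``: (n, C_out, k, k, C_in).  Each candidate is scaled
    elementwise along the spatial, input-channel and output-channel axes,
    then the candidates are combined with the simplex kernel weights.
    """
    kernels = np.asarray(kernels, dtype=np.float64)
    n, c_out, k, _, c_in = kernels.shape
    if attn.n_kernels != n:
        raise ConfigError("kernel-attention length does not match kernel count")
    if np.shape(attn.spatial) != (k, k):
        raise ConfigError("spatial attention shape mismatch")
    if np.shape(attn.in_channel) != (c_in,):
        raise ConfigError("input-channel attention shape mismatch")
    if np.shape(attn.out_channel) != (c_out,):
        raise ConfigError("output-channel attention shape mismatch")
    w = kernels * np.asarray(attn.spatial)[None, None, :, :, None]
    w = w * np.asarray(attn.in_channel)[None, None, None, None, :]
    w = w * np.asarray(attn.out_channel)[None, :, None, None, None]
    w = w * np.asarray(attn.kernel)[:, None, None, None, None]
    return w.sum(axis=0)


def odconv_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    attn: OdconvAttention,
    bias: np.ndarray | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Omni-dimensional dynamic convolution of a ``(H, W, C_in)`` tensor.

    With ``n = 1`` and all attention factors 1 this reduces exactly to a
    standard convolution with the single candidate kernel.
    """
    combined = combine_kernels(kernels, attn)
    return conv2d(x, combined, bias=bias, stride=stride, padding="same")


class ODConv:
    """ODConv layer: candidate kernels plus the attention head that gates them.

    The attention head follows the GAP -> bottleneck (reduction 4) -> four
    parallel linear heads design: softmax over kernels for the kernel
    attention, sigmoid for the spatial / input-channel / output-channel
    attentions.  Everything is computed per call from the input tensor.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        n_kernels: int = 4,
        stride: int = 1,
        reduction: int = 4,
        rng=None,
    ):
        if min(c_in, c_out, k, n_kernels) < 1:
            raise ConfigError("ODConv dimensions must be positive")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.n = c_in, c_out, k, n_kernels
        self.stride = stride
        scale = math.sqrt(2.0 / (k * k * c_in))
        self.kernels = rng.normal(0, scale, size=(n_kernels, c_out, k, k, c_in))
        self.bias = np.zeros(c_out)
        hidden = max(1, c_in // reduction)
        self.w_squeeze = rng.normal(0, math.sqrt(2.0 / c_in), size=(hidden, c_in))
        self.heads = {
            "kernel": rng.normal(0, 0.1, size=(n_kernels, hidden)),
            "spatial": rng.normal(0, 0.1, size=(k * k, hidden)),
            "in_channel": rng.normal(0, 0.1, size=(c_in, hidden)),
            "out_channel": rng.normal(0, 0.1, size=(c_out, hidden)),
        }

    @property
    def n_params(self) -> int:
        return (
            self.kernels.size
            + self.bias.size
            + self.w_squeeze.size
            + sum(h.size for h in self.heads.values())
        )

    def attention(self, x: np.ndarray) -> OdconvAttention:
        gap = np.asarray(x, dtype=np.float64).mean(axis=(0, 1))
        hidden = np.maximum(self.w_squeeze @ gap, 0.0)
        logits = self.heads["kernel"] @ hidden
        e = np.exp(logits - logits.max())
        return OdconvAttention(
            kernel=e / e.sum(),
            spatial=sigmoid(self.heads["spatial"] @ hidden).reshape(self.k, self.k),
            in_channel=sigmoid(self.heads["in_channel"] @ hidden),
            out_channel=sigmoid(self.heads["out_channel"] @ hidden),
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return odconv_forward(
            x, self.kernels, self.attention(x), bias=self.bias, stride=self.stride
        )
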