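"""Assembly of the improved one-stage seed detector (OEW variant).

The network is a YOLOv8n-scale anchor-free detector with three changes aimed
at small, partially cut seeds on cluttered soil:

* the cross-stage C2f blocks that hand features from the Backbone to the
  Neck use dynamic-convolution bottlenecks (``ODC_Bottleneck``: the second
  3x3 convolution is an ODConv),
* an ECA channel-attention block follows each Neck fusion stage,
* the box-regression loss is Wise-IoU v3 instead of CIoU.

This is a structural, NumPy inference-path implementation: the forward pass
produces the three prediction scales (strides 8/16/32) and the parameter
count, and the loss registry wires either box loss.  Full-scale gradient
training is out of scope here; the training configuration preset mirrors the
published schedule (SGD, lr 0.01, batch 32, 200 epochs, 640 px input), and
:func:`fit_box_demo` exercises loss convergence at desk scale via
finite-difference descent on the box parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError
from .blocks import ECA, ODConv, conv2d
from .losses import BBox, LossState, ciou_loss, wiou_v3

#: training schedule preset for the full-scale detector
TRAINING_PRESET = {
    "optimizer": "SGD",
    "lr0": 0.01,
    "batch_size": 32,
    "epochs": 200,
    "workers": 2,
    "input_size": 640,
    "box_loss": "wiou_v3",
    "cls_loss": "bce",
}


def silu(x):
    return x / (1.0 + np.exp(-x))


class Conv:
    """3x3 (or 1x1) convolution + SiLU, He-initialized."""

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None, act=True):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (k * k * c_in))
        self.weight = rng.normal(0, scale, size=(c_out, k, k, c_in)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self.act = act

    @property
    def n_params(self):
        return self.weight.size + self.bias.size

    def __call__(self, x):
        y = conv2d(x, self.weight, self.bias, stride=self.stride, padding="same")
        return silu(y) if self.act else y


class Bottleneck:
    """Two 3x3 convolutions with a residual connection."""

    def __init__(self, c, rng, odconv=False):
        self.cv1 = Conv(c, c, 3, rng=rng)
        # ODC_Bottleneck: the second conv becomes a dynamic convolution
        self.cv2 = ODConv(c, c, 3, rng=rng) if odconv else Conv(c, c, 3, rng=rng)
        self.odconv = odconv

    @property
    def n_params(self):
        return self.cv1.n_params + self.cv2.n_params

    def __call__(self, x):
        y = self.cv2(self.cv1(x))
        if not self.odconv:
            return x + y
        return x + silu(y)


class C2f:
    """Cross-stage partial block: split, n bottlenecks, concat, fuse.

    With ``odconv=True`` this is the ODC_C2f variant used where the
    Backbone hands off to the Neck.
    """

    def __init__(self, c_in, c_out, n=1, rng=None, odconv=False):
        rng = rng or np.random.default_rng(0)
        self.c_hidden = c_out // 2
        self.cv1 = Conv(c_in, 2 * self.c_hidden, 1, rng=rng)
        self.blocks = [Bottleneck(self.c_hidden, rng, odconv=odconv) for _ in range(n)]
        self.cv2 = Conv((2 + n) * self.c_hidden, c_out, 1, rng=rng)
        self.odconv = odconv

    @property
    def n_params(self):
        return self.cv1.n_params + self.cv2.n_params + sum(b.n_params for b in self.blocks)

    def __call__(self, x):
        y = self.cv1(x)
        parts = [y[..., : self.c_hidden], y[..., self.c_hidden :]]
        for blk in self.blocks:
            parts.append(blk(parts[-1]))
        return self.cv2(np.concatenate(parts, axis=-1))


def _maxpool_same(x, k=5):
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
    return win.max(axis=(-2, -1))


class SPPF:
    """Spatial pyramid pooling (fast): cascaded 5x5 max-pools, concat, fuse."""

    def __init__(self, c, rng):
        self.cv1 = Conv(c, c // 2, 1, rng=rng)
        self.cv2 = Conv(2 * c, c, 1, rng=rng)

    @property
    def n_params(self):
        return self.cv1.n_params + self.cv2.n_params

    def __call__(self, x):
        y = self.cv1(x)
        p1 = _maxpool_same(y)
        p2 = _maxpool_same(p1)
        p3 = _maxpool_same(p2)
        return self.cv2(np.concatenate([y, p1, p2, p3], axis=-1))


def _upsample2(x):
    return x.repeat(2, axis=0).repeat(2, axis=1)


@dataclass
class Detector:
    """Assembled detector: ordered stages plus the box-loss callable."""

    stem: list
    backbone: dict
    neck: dict
    heads: dict
    box_loss_name: str
    loss_state: LossState = field(default_factory=LossState)

    @property
    def parameter_count(self) -> int:
        total = sum(layer.n_params for layer in self.stem)
        for group in (self.backbone, self.neck, self.heads):
            for layers in group.values():
                total += sum(layer.n_params for layer in layers)
        return total

    def box_loss(self, pred: BBox, gt: BBox) -> float:
        if self.box_loss_name == "ciou":
            return ciou_loss(pred, gt)
        loss, self.loss_state = wiou_v3(pred, gt, self.loss_state)
        return loss

    def forward(self, image: np.ndarray) -> dict[int, np.ndarray]:
        """Run the network; returns ``{stride: (H/s, W/s, 5)}`` feature maps.

        The 5 output channels per location are (cx, cy, w, h, objectness)
        for the single "seed" class.  Input height/width must be multiples
        of 32.
        """
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = x[..., None].repeat(3, axis=-1)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ConfigError("detector input must be (H, W, 3) or grayscale")
        if x.shape[0] % 32 or x.shape[1] % 32:
            raise ConfigError("input height and width must be multiples of 32")
        for layer in self.stem:
            x = layer(x)
        feats = {}
        for name, layers in self.backbone.items():
            for layer in layers:
                x = layer(x)
            feats[name] = x
        p3, p4, p5 = feats["p3"], feats["p4"], feats["p5"]

        nk = self.neck
        t4 = nk["fuse_p4"][0](np.concatenate([_upsample2(p5), p4], axis=-1))
        t4 = nk["fuse_p4"][1](t4)
        t3 = nk["fuse_p3"][0](np.concatenate([_upsample2(t4), p3], axis=-1))
        t3 = nk["fuse_p3"][1](t3)
        d4 = nk["down_p4"][0](t3)
        t4b = nk["down_p4"][1](np.concatenate([d4, t4], axis=-1))
        t4b = nk["down_p4"][2](t4b)
        d5 = nk["down_p5"][0](t4b)
        t5b = nk["down_p5"][1](np.concatenate([d5, p5], axis=-1))
        t5b = nk["down_p5"][2](t5b)

        return {
            8: self.heads["p3"][0](t3),
            16: self.heads["p4"][0](t4b),
            32: self.heads["p5"][0](t5b),
        }


def assemble_oew_yolov8n(
    width_mult: float = 0.25,
    depth_mult: float = 1 / 3,
    box_loss: str = "wiou_v3",
    seed: int = 0,
) -> Detector:
    """Build the improved detector at the given width/depth scale.

    Defaults are the nano scale (width 0.25, depth 1/3 of the base 64-channel
    / 3-repeat design).  ``box_loss`` selects "wiou_v3" (default) or "ciou";
    swapping it changes only the regression-loss value, never tensor shapes.
    """
    if box_loss not in ("wiou_v3", "ciou"):
        raise ConfigError(f"unknown box loss {box_loss!r}")
    if width_mult <= 0 or depth_mult <= 0:
        raise ConfigError("width/depth multipliers must be positive")
    rng = np.random.default_rng(seed)
    ch = [max(2, int(round(c * width_mult))) for c in (64, 128, 256, 512, 1024)]
    c1, c2, c3, c4, c5 = ch
    n_shallow = max(1, round(3 * depth_mult))
    n_deep = max(1, round(6 * depth_mult))

    stem = [Conv(3, c1, 3, stride=2, rng=rng)]
    backbone = {
        # ODC_C2f at every Backbone->Neck junction (p3, p4, p5)
        "p3": [
            Conv(c1, c2, 3, stride=2, rng=rng),
            C2f(c2, c2, n_shallow, rng=rng),
            Conv(c2, c3, 3, stride=2, rng=rng),
            C2f(c3, c3, n_deep, rng=rng, odconv=True),
        ],
        "p4": [
            Conv(c3, c4, 3, stride=2, rng=rng),
            C2f(c4, c4, n_deep, rng=rng, odconv=True),
        ],
        "p5": [
            Conv(c4, c5, 3, stride=2, rng=rng),
            C2f(c5, c5, n_shallow, rng=rng, odconv=True),
            SPPF(c5, rng),
        ],
    }
    neck = {
        "fuse_p4": [C2f(c5 + c4, c4, n_shallow, rng=rng), ECA(c4, rng=rng)],
        "fuse_p3": [C2f(c4 + c3, c3, n_shallow, rng=rng), ECA(c3, rng=rng)],
        "down_p4": [
            Conv(c3, c3, 3, stride=2, rng=rng),
            C2f(c3 + c4, c4, n_shallow, rng=rng),
            ECA(c4, rng=rng),
        ],
        "down_p5": [
            Conv(c4, c4, 3, stride=2, rng=rng),
            C2f(c4 + c5, c5, n_shallow, rng=rng),
            ECA(c5, rng=rng),
        ],
    }
    heads = {
        "p3": [Conv(c3, 5, 1, rng=rng, act=False)],
        "p4": [Conv(c4, 5, 1, rng=rng, act=False)],
        "p5": [Conv(c5, 5, 1, rng=rng, act=False)],
    }
    return Detector(stem=stem, backbone=backbone, neck=neck, heads=heads,
                    box_loss_name=box_loss)


def fit_box_demo(
    gt: BBox | None = None,
    start: BBox | None = None,
    steps: int = 20,
    lr: float = 0.05,
    loss: str = "wiou_v3",
) -> list[float]:
    """Desk-scale loss-convergence check: regress one box onto a target.

    Runs ``steps`` iterations of finite-difference gradient descent on the
    box parameters under the selected loss and returns the per-step loss
    trajectory (which should decrease).
    """
    gt = gt or BBox(0.5, 0.5, 0.2, 0.1)
    start = start or BBox(0.35, 0.6, 0.3, 0.08)
    state = LossState()

    def evaluate(params):
        b = BBox(*params)
        if loss == "ciou":
            return ciou_loss(b, gt)
        return wiou_v3(b, gt, state)[0]

    params = np.array([start.cx, start.cy, start.w, start.h], dtype=float)
    history = []
    eps = 1e-5
    for _ in range(steps):
        f0 = evaluate(params)
        history.append(f0)
        grad = np.zeros(4)
        for i in range(4):
            p = params.copy()
            p[i] += eps
            grad[i] = (evaluate(p) - f0) / eps
        params -= lr * grad
        params[2:] = np.maximum(params[2:], 1e-4)
        # advance the running mean as a training loop would
        if loss == "wiou_v3":
            _, state = wiou_v3(BBox(*params), gt, state)
    history.append(evaluate(params))
    return history
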