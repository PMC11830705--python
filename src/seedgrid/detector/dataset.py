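"""Dataset utilities: augmentation, 7:2:1 splitting, experiment layout.

The tile dataset construction mirrors the published protocol: 18 training
photographs (2 per sowing mode) are tiled into (738 + 864 + 1044) x 3 x 2 =
15,876 unit seed-grid images, augmented by a factor of 1.5 to 23,814, and
split 7:2:1 into train/val/test (16,669 / 4,763 / 2,382).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from ..errors import ConfigError
from .losses import BBox

AUGMENT_OPS = (
    "crop",
    "gauss_noise",
    "hflip",
    "vflip",
    "color",
    "contrast",
    "scale",
)


@dataclass(frozen=True, eq=False)
class LabeledImage:
    """One tile image with its normalized box labels."""

    image: np.ndarray
    boxes: tuple = ()  # (class_id, BBox) pairs, normalized tile frame
    name: str = ""
    augmented_from: str | None = None


def experiment_photo_counts(
    modes: int = 9,
    trays_per_mode: int = 5,
    photos_per_tray: int = 5,
    training_photos_per_mode: int = 2,
) -> dict[str, int]:
    """Photograph bookkeeping of the sowing experiment layout.

    Nine sowing modes (3 densities x 3 methods), 5 trays each, 5 valid
    photographs per tray; 2 photographs per mode train the detector and the
    rest evaluate uniformity in application.
    """
    total = modes * trays_per_mode * photos_per_tray
    training = modes * training_photos_per_mode
    return {"total": total, "training": training, "application": total - training}


def training_tile_count(grid_totals=(738, 864, 1044), methods: int = 3,
                        photos_per_mode: int = 2) -> int:
    """Unit seed-grid tiles cut from the training photographs."""
    return sum(grid_totals) * methods * photos_per_mode


def augmented_size(n: int, multiplier: float = 1.5) -> int:
    """Dataset size after augmentation: round(multiplier * n), originals kept."""
    if multiplier < 1:
        raise ConfigError("augmentation multiplier must be >= 1")
    return int(round(multiplier * n))


# --- box-aware transforms ----------------------------------------------


def hflip_box(box: BBox) -> BBox:
    return replace(box, cx=1.0 - box.cx)


def vflip_box(box: BBox) -> BBox:
    return replace(box, cy=1.0 - box.cy)


def _clip_box_to_window(box: BBox, x0, y0, x1, y1) -> BBox | None:
    """Re-express a normalized box inside window [x0,x1]x[y0,y1]; None if gone."""
    lo_x, hi_x = max(box.x_lo, x0), min(box.x_hi, x1)
    lo_y, hi_y = max(box.y_lo, y0), min(box.y_hi, y1)
    if hi_x <= lo_x or hi_y <= lo_y:
        return None
    sx, sy = x1 - x0, y1 - y0
    return BBox.from_corners(
        (lo_x - x0) / sx, (lo_y - y0) / sy, (hi_x - x0) / sx, (hi_y - y0) / sy,
        frame=box.frame,
    )


def _apply_transform(item: LabeledImage, op: str, rng: np.random.Generator) -> LabeledImage:
    img = np.asarray(item.image, dtype=float)
    h, w = img.shape[:2]
    boxes = list(item.boxes)
    if op == "hflip":
        img = img[:, ::-1].copy()
        boxes = [(c, hflip_box(b)) for c, b in boxes]
    elif op == "vflip":
        img = img[::-1, :].copy()
        boxes = [(c, vflip_box(b)) for c, b in boxes]
    elif op == "gauss_noise":
        img = np.clip(img + rng.normal(0, 8.0, size=img.shape), 0, 255)
    elif op == "color":
        img = np.clip(img + rng.uniform(-30, 30), 0, 255)
    elif op == "contrast":
        f = rng.uniform(0.75, 1.25)
        img = np.clip((img - 128.0) * f + 128.0, 0, 255)
    elif op == "scale":
        fx, fy = rng.uniform(0.8, 1.2, size=2)
        new_shape = (max(4, int(round(h * fy))), max(4, int(round(w * fx))))
        img = resize(img, new_shape, preserve_range=True, anti_aliasing=False)
        # normalized coordinates are scale-invariant
    elif op == "crop":
        fw, fh = rng.uniform(0.7, 0.95, size=2)
        x0 = rng.uniform(0, 1 - fw)
        y0 = rng.uniform(0, 1 - fh)
        x1, y1 = x0 + fw, y0 + fh
        r0, r1 = int(round(y0 * h)), int(round(y1 * h))
        c0, c1 = int(round(x0 * w)), int(round(x1 * w))
        img = img[r0:r1, c0:c1].copy()
        kept = []
        for c, b in boxes:
            nb = _clip_box_to_window(b, x0, y0, x1, y1)
            if nb is not None:
                kept.append((c, nb))
        boxes = kept
    else:
        raise ConfigError(f"unknown augmentation op {op!r}")
    return LabeledImage(
        image=img, boxes=tuple(boxes),
        name=f"{item.name}_{op}", augmented_from=item.name or None,
    )


def augment(dataset, multiplier: float = 1.5, seed: int = 0) -> list[LabeledImage]:
    """Expand a tile dataset to ``round(multiplier * N)`` images.

    Originals are retained; each added image is one randomly chosen
    transform (crop, Gaussian noise, horizontal/vertical flip, color shift,
    contrast change, random rescale) of a random original, with box labels
    remapped consistently.  A crop that drops every box of a labelled image
    is resampled.
    """
    dataset = list(dataset)
    n_extra = augmented_size(len(dataset), multiplier) - len(dataset)
    rng = np.random.default_rng(seed)
    out = list(dataset)
    for i in range(n_extra):
        for _ in range(100):
            src = dataset[rng.integers(len(dataset))]
            op = AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))]
            new = _apply_transform(src, op, rng)
            if src.boxes and not new.boxes:
                continue  # all boxes dropped: resample
            break
        out.append(replace(new, name=f"{new.name}_{i}"))
    return out


def split_dataset(dataset, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Seeded random 7:2:1 (by default) train/val/test partition.

    Validation and test sizes are ``ceil(ratio * N)``; training takes the
    remainder.  The three parts are disjoint and cover the input.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3:
        raise ConfigError("ratios must have three entries")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must sum to 1, got {sum(ratios)}")
    items = list(dataset)
    n = len(items)
    n_val = min(n, math.ceil(ratios[1] * n))
    n_test = min(n - n_val, math.ceil(ratios[2] * n))
    order = np.random.default_rng(seed).permutation(n)
    val = [items[i] for i in order[:n_val]]
    test = [items[i] for i in order[n_val : n_val + n_test]]
    train = [items[i] for i in order[n_val + n_test :]]
    return train, val, test
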