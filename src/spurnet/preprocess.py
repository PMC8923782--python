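"""Resizing, normalization, augmentation and shuffling of image/mask pairs.

The canonical training resolution is 256×256. Raw 8-bit values v are mapped
to the symmetric interval [−1, +1] by v ↦ 2·v/255 − 1. Augmentation applies
one random similarity transform (rotation up to ±10°, horizontal/vertical
shifts up to ±0.2 of the side, independent horizontal/vertical flips) to the
image and its mask identically, plus an additive per-channel color shift on
the image only. Pixels exposed by the geometric transform are filled with
the nearest edge value in the image and with background (0) in the mask, so
augmentation can never create phantom tongue pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .io_formats import NORMALIZED, RAW8BIT, RgbImage, SegMask

CANONICAL_SIDE = 256


@dataclass
class AugmentConfig:
    """Augmentation ranges. Shift ranges are fractions of the image side;
    the channel shift is a fraction of the value range."""

    rotation_range: float = 10.0
    width_shift_range: float = 0.2
    height_shift_range: float = 0.2
    channel_shift_range: float = 0.2
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self):
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        for name in ("width_shift_range", "height_shift_range", "channel_shift_range"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        return cls(**d)


def resize_to_canonical(
    img: RgbImage, mask: SegMask | None = None, side: int = CANONICAL_SIDE
):
    """Resize to side×side: bilinear for the image, nearest for the mask."""
    if side <= 0:
        raise ValueError("side must be positive")
    if img.height == side and img.width == side:
        out_img = img
    else:
        if img.value_range == RAW8BIT:
            px = _sk_resize(
                img.pixels.astype(float), (side, side), order=1, anti_aliasing=True
            )
            out_img = RgbImage(np.clip(np.rint(px), 0, 255).astype(np.uint8), RAW8BIT)
        else:
            px = _sk_resize(img.pixels, (side, side), order=1, anti_aliasing=True)
            out_img = RgbImage(np.clip(px, -1.0, 1.0), NORMALIZED)
    if mask is None:
        return out_img, None
    if mask.shape == (side, side):
        return out_img, mask
    lab = _sk_resize(
        mask.labels, (side, side), order=0, preserve_range=True, anti_aliasing=False
    )
    return out_img, SegMask(lab.astype(np.uint8))


def normalize(img: RgbImage) -> RgbImage:
    """Map raw 8-bit values to [−1, +1] via v ↦ 2·v/255 − 1."""
    if img.value_range != RAW8BIT:
        raise ValueError("image is already normalized")
    px = 2.0 * img.pixels.astype(np.float32) / 255.0 - 1.0
    return RgbImage(px, NORMALIZED)


def denormalize(img: RgbImage) -> RgbImage:
    """Inverse of :func:`normalize`, back to raw 8-bit."""
    if img.value_range != NORMALIZED:
        raise ValueError("image is not normalized")
    px = np.clip(np.rint((img.pixels + 1.0) * 255.0 / 2.0), 0, 255).astype(np.uint8)
    return RgbImage(px, RAW8BIT)


def sample_transform_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters. Exposed separately so the
    sampled values can be audited against the configured ranges."""
    return {
        "rotation_deg": rng.uniform(-cfg.rotation_range, cfg.rotation_range),
        "width_shift": rng.uniform(-cfg.width_shift_range, cfg.width_shift_range),
        "height_shift": rng.uniform(-cfg.height_shift_range, cfg.height_shift_range),
        "channel_shift": rng.uniform(
            -cfg.channel_shift_range, cfg.channel_shift_range, size=3
        ),
        "hflip": bool(cfg.horizontal_flip and rng.random() < 0.5),
        "vflip": bool(cfg.vertical_flip and rng.random() < 0.5),
    }


def _apply_geometric(arr, rotation_deg, dy, dx, order, mode, cval):
    """Rotate about the center then translate, in one resampling pass."""
    h, w = arr.shape[:2]
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # output coord y maps to input coord rot^T @ (y - center - t) + center
    offset = center - rot.T @ (center + np.array([dy, dx]))
    out = np.empty_like(arr)
    if arr.ndim == 2:
        return ndimage.affine_transform(
            arr, rot.T, offset=offset, order=order, mode=mode, cval=cval
        )
    for ch in range(arr.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            arr[..., ch], rot.T, offset=offset, order=order, mode=mode, cval=cval
        )
    return out


def augment_pair(
    img: RgbImage,
    mask: SegMask,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    params: dict | None = None,
):
    """Apply one random augmentation identically to an image and its mask.

    The mask stays binary and keeps its shape; the channel shift touches the
    image only. With all ranges zero and flips disabled the pair is returned
    unchanged (exact identity). ``params`` overrides the random draw, which
    otherwise consumes values from ``rng`` only.
    """
    if (img.height, img.width) != mask.shape:
        raise ValueError(f"image {img.height}×{img.width} vs mask {mask.shape}")
    if params is None:
        params = sample_transform_params(cfg, rng)

    px = img.pixels
    lab = mask.labels
    if params["hflip"]:
        px, lab = px[:, ::-1], lab[:, ::-1]
    if params["vflip"]:
        px, lab = px[::-1, :], lab[::-1, :]

    dy = params["height_shift"] * px.shape[0]
    dx = params["width_shift"] * px.shape[1]
    if params["rotation_deg"] != 0.0 or dy != 0.0 or dx != 0.0:
        px = _apply_geometric(
            px.astype(np.float32), params["rotation_deg"], dy, dx, 1, "nearest", 0.0
        )
        lab = _apply_geometric(lab, params["rotation_deg"], dy, dx, 0, "constant", 0)
    else:
        px = px.astype(np.float32) if img.value_range == NORMALIZED else px.copy()
        lab = lab.copy()

    shift = np.asarray(params["channel_shift"], dtype=np.float32)
    if np.any(shift != 0.0):
        if img.value_range == NORMALIZED:
            px = np.clip(px + shift[None, None, :], -1.0, 1.0)
        else:
            px = np.clip(px.astype(np.float32) + shift[None, None, :] * 255.0, 0, 255)
    if img.value_range == RAW8BIT:
        px = np.clip(np.rint(np.asarray(px, dtype=np.float32)), 0, 255).astype(np.uint8)
    else:
        px = np.clip(px, -1.0, 1.0)
    return RgbImage(px, img.value_range), SegMask((np.asarray(lab) > 0).astype(np.uint8))


def shuffle_dataset(pairs: list, rng: np.random.Generator) -> list:
    """Return a random permutation of the dataset (stable for a fixed rng)."""
    pairs = list(pairs)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]
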