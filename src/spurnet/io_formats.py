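"""Image, mask, polygon-annotation and checkpoint I/O.

All other modules consume the types defined here. Images are H×W×3 numpy
rasters tagged with their value range (raw 8-bit or normalized to [−1, +1]);
masks are H×W integer rasters with 0 = background, 1 = tongue. Polygon
annotations follow the Labelme JSON dialect used to outline tongue contours:
``{"shapes": [{"label": ..., "points": [[x, y], ...]}, ...],
"imageHeight": ..., "imageWidth": ...}`` with (x, y) = (column, row) float
pixel coordinates. Internally everything is 0-based (row, col).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from PIL import Image, UnidentifiedImageError

RAW8BIT = "raw8bit"
NORMALIZED = "normalized"


class FormatError(ValueError):
    """A file exists but cannot be decoded as the expected format."""


@dataclass
class RgbImage:
    """An H×W×3 color raster plus its declared value range."""

    pixels: np.ndarray
    value_range: str = RAW8BIT

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        if self.value_range not in (RAW8BIT, NORMALIZED):
            raise ValueError(f"unknown value_range {self.value_range!r}")
        if self.value_range == RAW8BIT:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("raw8bit pixels must lie in [0, 255]")
        else:
            if self.pixels.min() < -1.0 - 1e-6 or self.pixels.max() > 1.0 + 1e-6:
                raise ValueError("normalized pixels must lie in [-1, +1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SegMask:
    """Binary label raster: 0 = background, 1 = tongue."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected H×W labels, got shape {self.labels.shape}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("mask labels must be 0 or 1")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class PolygonAnnotation:
    """Labelme-style annotation: named polygons over one image."""

    shapes: list[tuple[str, np.ndarray]]  # (category, (V,2) array of (x, y))
    image_height: int
    image_width: int

    def __post_init__(self):
        cleaned = []
        for label, pts in self.shapes:
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"polygon {label!r}: points must be (V, 2)")
            if pts.shape[0] < 3:
                raise ValueError(f"polygon {label!r} has fewer than 3 vertices")
            # clip stray vertices to the canvas
            pts[:, 0] = np.clip(pts[:, 0], 0, self.image_width - 1)
            pts[:, 1] = np.clip(pts[:, 1], 0, self.image_height - 1)
            cleaned.append((str(label), pts))
        self.shapes = cleaned

    @property
    def category_names(self) -> set[str]:
        return {label for label, _ in self.shapes}


# ---------------------------------------------------------------------------
# images and masks


def read_image(path) -> RgbImage:
    """Read a PNG/JPEG file as a raw 8-bit RGB image.

    Grayscale inputs are replicated to 3 channels; an alpha channel is
    dropped. Missing files raise ``FileNotFoundError``; undecodable files
    raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode {path} as an image: {exc}") from exc
    return RgbImage(arr, RAW8BIT)


def write_image(img: RgbImage, path) -> None:
    """Write a raw 8-bit image as PNG/JPEG (by extension)."""
    if img.value_range != RAW8BIT:
        raise ValueError("write_image expects a raw8bit image")
    Image.fromarray(img.pixels.astype(np.uint8)).save(path)


def write_mask(mask: SegMask, path, visual: bool = False) -> None:
    """Write a mask as a single-channel PNG.

    By default values are stored as {0, 1}; with ``visual=True`` they are
    scaled to {0, 255} for direct viewing.
    """
    arr = mask.labels.astype(np.uint8)
    if visual:
        arr = arr * 255
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path) -> SegMask:
    """Read a single-channel PNG mask; any nonzero pixel becomes label 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode {path} as a mask: {exc}") from exc
    return SegMask((arr > 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# polygon annotations


def read_annotation(source) -> PolygonAnnotation:
    """Parse a Labelme-dialect JSON file (or an already-loaded dict)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"cannot parse {path} as JSON: {exc}") from exc
    else:
        payload = source
    try:
        shapes = [(s["label"], np.asarray(s["points"], dtype=float)) for s in payload["shapes"]]
        h, w = int(payload["imageHeight"]), int(payload["imageWidth"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a Labelme-dialect annotation: {exc}") from exc
    return PolygonAnnotation(shapes, h, w)


def annotation_to_mask(
    ann: PolygonAnnotation, positive_label: str = "tongue", allow_empty: bool = False
) -> SegMask:
    """Rasterize every polygon named ``positive_label`` into a binary mask.

    A pixel is foreground when its center lies inside or on the boundary of
    any matching polygon (boundary-inclusive); polygons are unioned. Unknown
    category names are ignored so multi-class files degrade to binary.
    """
    polys = [pts for label, pts in ann.shapes if label == positive_label]
    if not polys and not allow_empty:
        raise ValueError(
            f"no polygon named {positive_label!r} (categories: {sorted(ann.category_names)}); "
            "pass allow_empty=True for an all-background mask"
        )
    mask = np.zeros((ann.image_height, ann.image_width), dtype=np.uint8)
    if polys:
        cols, rows = np.meshgrid(np.arange(ann.image_width), np.arange(ann.image_height))
        xs, ys = cols.ravel().astype(float), rows.ravel().astype(float)
        for pts in polys:
            poly = shapely.Polygon(pts)
            if not poly.is_valid:
                poly = poly.buffer(0)
            inside = shapely.intersects_xy(poly, xs, ys)  # covers boundary points
            mask.ravel()[inside] = 1
    return SegMask(mask)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: dict, path) -> None:
    """Serialize a model state (config dict + named float arrays) to .npz."""
    arrays = {f"param/{k}": v for k, v in state["params"].items()}
    arrays.update({f"buffer/{k}": v for k, v in state.get("buffers", {}).items()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(state.get("config", {})).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> dict:
    """Inverse of :func:`save_checkpoint`; round-trips bitwise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        params = {k[6:]: npz[k] for k in npz.files if k.startswith("param/")}
        buffers = {k[7:]: npz[k] for k in npz.files if k.startswith("buffer/")}
        config = json.loads(bytes(npz["config_json"]).decode()) if "config_json" in npz.files else {}
    return {"config": config, "params": params, "buffers": buffers}
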