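"""Synthetic tongue scenes with exact ground truth.

Clinical tongue photographs cannot be redistributed, so every stage of the
pipeline is exercised on rendered stand-ins: a noisy skin-toned background,
an elliptical reddish "tongue", and a "lip" crescent hugging the tongue's
upper margin whose mean color sits a controlled Euclidean distance
(``lip_tongue_color_gap``) from the tongue color — small gaps reproduce the
hard case where the tongue color is close to the adjoining area and the
segmentation boundary blurs. The ground-truth mask is the exact set of
pixel centers inside the tongue ellipse, so a perfect predictor scores
exactly 1.0 on every metric.

``corrupt_mask`` emulates the error modes of a coarse CNN mask: a smooth
bounded displacement of the boundary (over-/under-segmentation at the
margin) plus small disk-shaped speckles of flipped labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_formats import RgbImage, SegMask


@dataclass
class SceneSpec:
    side: int = 256
    tongue_axes: tuple = (0.22, 0.17)  # (vertical, horizontal) semi-axes / side
    tongue_center: tuple = (0.58, 0.5)  # (row, col) / side
    tongue_color: tuple = (176, 58, 70)
    background_color: tuple = (126, 112, 104)
    lip_tongue_color_gap: float = 40.0
    lip_thickness: float = 0.3  # relative widening of the ellipse for the lip ring
    texture_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("tongue_color", "background_color"):
            if not all(0 <= v <= 255 for v in getattr(self, name)):
                raise ValueError(f"{name} components must lie in [0, 255]")
        if not all(0 < a < 0.5 for a in self.tongue_axes):
            raise ValueError("tongue_axes must be fractions in (0, 0.5)")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")
        if self.lip_tongue_color_gap < 0:
            raise ValueError("lip_tongue_color_gap must be >= 0")

    @property
    def lip_color(self) -> np.ndarray:
        """Tongue color displaced by exactly lip_tongue_color_gap."""
        direction = np.array([-0.2, 0.8, 0.6])
        direction /= np.linalg.norm(direction)
        return np.clip(
            np.array(self.tongue_color, float) + self.lip_tongue_color_gap * direction,
            0,
            255,
        )


@dataclass
class CorruptionSpec:
    boundary_jitter_px: float = 3.0
    speckle_count: int = 5
    speckle_radius_px: int = 2
    jitter_smoothness: float = 8.0  # gaussian sigma of the displacement field
    seed: int = 0

    def __post_init__(self):
        if min(self.boundary_jitter_px, self.speckle_count, self.speckle_radius_px) < 0:
            raise ValueError("corruption amounts must be >= 0")


def _ellipse_rho(side: int, center, axes) -> np.ndarray:
    """Normalized elliptic radius of every pixel center (1.0 on the rim)."""
    rows = np.arange(side)[:, None]
    cols = np.arange(side)[None, :]
    cy, cx = center[0] * side, center[1] * side
    ay, ax = axes[0] * side, axes[1] * side
    return np.sqrt(((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2)


def generate_scene(spec: SceneSpec | None = None) -> tuple[RgbImage, SegMask]:
    """Render one scene; deterministic for a fixed spec (including seed)."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    rho = _ellipse_rho(side, spec.tongue_center, spec.tongue_axes)
    tongue = rho <= 1.0  # exact point-in-ellipse test at pixel centers
    # lip crescent: a ring just outside the tongue, upper half only
    ring = (rho > 1.0) & (rho <= 1.0 + spec.lip_thickness)
    rows = np.arange(side)[:, None]
    upper = rows < spec.tongue_center[0] * side
    lip = ring & np.broadcast_to(upper, ring.shape)

    img = np.empty((side, side, 3), float)
    img[:] = spec.background_color
    img[lip] = spec.lip_color
    img[tongue] = spec.tongue_color
    if spec.texture_noise_sd > 0:
        img += rng.normal(0.0, spec.texture_noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RgbImage(img), SegMask(tongue.astype(np.uint8))


def corrupt_mask(mask: SegMask, spec: CorruptionSpec | None = None) -> SegMask:
    """Degrade a clean mask the way a coarse CNN prediction is degraded.

    The boundary is displaced by thresholding (signed distance + smooth
    noise field); the field is rescaled so its maximum magnitude is the
    jitter bound, hence no flipped pixel lies farther than
    ``boundary_jitter_px`` from the original boundary. Speckle disks are
    then flipped wholesale. All randomness comes from ``spec.seed``.
    """
    spec = spec or CorruptionSpec()
    rng = np.random.default_rng(spec.seed)
    lab = mask.labels.astype(bool)
    if spec.boundary_jitter_px > 0 and lab.any() and not lab.all():
        # signed distance: positive inside the tongue, negative outside
        sdt = ndimage.distance_transform_edt(lab) - ndimage.distance_transform_edt(~lab)
        noise = ndimage.gaussian_filter(
            rng.standard_normal(lab.shape), spec.jitter_smoothness
        )
        peak = np.abs(noise).max()
        if peak > 0:
            noise *= spec.boundary_jitter_px / peak
        lab = (sdt + noise) > 0
    if spec.speckle_count > 0:
        r = spec.speckle_radius_px
        h, w = lab.shape
        dy, dx = np.ogrid[-r : r + 1, -r : r + 1]
        disk = dy**2 + dx**2 <= r**2
        for _ in range(spec.speckle_count):
            cy = int(rng.integers(r, h - r))
            cx = int(rng.integers(r, w - r))
            patch = lab[cy - r : cy + r + 1, cx - r : cx + r + 1]
            patch[disk] = ~patch[disk]
    return SegMask(lab.astype(np.uint8))


def generate_dataset(
    n: int,
    seed: int = 0,
    side: int = 256,
    axes_range: tuple = ((0.16, 0.26), (0.13, 0.21)),
    center_range: tuple = ((0.5, 0.65), (0.42, 0.58)),
    gap_range: tuple = (25.0, 60.0),
    noise_range: tuple = (4.0, 10.0),
    return_specs: bool = False,
):
    """Draw n scenes with per-scene parameters sampled from the ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out, specs = [], []
    for _ in range(n):
        spec = SceneSpec(
            side=side,
            tongue_axes=(
                rng.uniform(*axes_range[0]),
                rng.uniform(*axes_range[1]),
            ),
            tongue_center=(
                rng.uniform(*center_range[0]),
                rng.uniform(*center_range[1]),
            ),
            lip_tongue_color_gap=rng.uniform(*gap_range),
            texture_noise_sd=rng.uniform(*noise_range),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
        out.append(generate_scene(spec))
    if return_specs:
        return out, specs
    return out


def dataset_manifest(specs: list[SceneSpec]) -> list[dict]:
    """JSON-serializable record of every spec used to build a dataset."""
    return [asdict(s) for s in specs]
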