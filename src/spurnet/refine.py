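"""Superpixel coverage-threshold refinement (SpurNet stage 2).

The coarse CNN mask is revised one superpixel block at a time: for each
block the tongue coverage — the fraction of its pixels the coarse mask
labels 1 — is compared against a threshold θ. Blocks whose coverage exceeds
θ (strictly) survive; all pixels of the remaining blocks are reset to
background. Two survival semantics are provided, because "retained" is
ambiguous between them:

* ``retain`` — surviving blocks keep their coarse labels unchanged; the
  refined tongue is a subset of the coarse tongue (it only removes spill).
* ``fill`` — surviving blocks are set entirely to tongue, which can also
  repair under-segmentation at the margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import RgbImage, SegMask
from .slic import SlicParams, SuperpixelLabeling, slic


@dataclass
class RefineParams:
    """θ is the tongue-coverage threshold a block must exceed to survive."""

    theta: float = 0.5
    mode: str = "retain"
    slic_params: SlicParams = field(default_factory=SlicParams)

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.mode not in ("retain", "fill"):
            raise ValueError("mode must be 'retain' or 'fill'")


def block_coverage(sp: SuperpixelLabeling, mask: SegMask) -> np.ndarray:
    """Per-block tongue coverage: #(mask==1 in block) / #(block)."""
    if sp.shape != mask.shape:
        raise ValueError(f"labeling {sp.shape} vs mask {mask.shape}")
    total = np.bincount(sp.labels.ravel(), minlength=sp.n_blocks)
    tongue = np.bincount(
        sp.labels.ravel(), weights=mask.labels.ravel().astype(float), minlength=sp.n_blocks
    )
    return tongue / np.maximum(total, 1)


def refine_mask(mask: SegMask, sp: SuperpixelLabeling, params: RefineParams) -> SegMask:
    """Apply the coverage rule to every block; see the module docstring."""
    cov = block_coverage(sp, mask)
    survives = cov > params.theta  # strict: coverage must exceed θ
    survive_px = survives[sp.labels]
    if params.mode == "retain":
        out = np.where(survive_px, mask.labels, 0)
    else:  # fill
        out = np.where(survive_px, 1, 0)
    return SegMask(out.astype(np.uint8))


def spurnet_segment(
    img: RgbImage, model, params: RefineParams | None = None
) -> tuple[SegMask, SegMask, SuperpixelLabeling]:
    """Full two-stage segmentation of one normalized canonical image.

    Returns ``(refined, coarse, superpixels)`` so callers can inspect the
    intermediate products. Superpixels are computed on the image itself, not
    on the coarse mask.
    """
    from .urnet import predict_mask  # local import to avoid a cycle

    params = params or RefineParams()
    coarse = predict_mask(model, img)
    sp = slic(img, params.slic_params)
    refined = refine_mask(coarse, sp, params)
    return refined, coarse, sp
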