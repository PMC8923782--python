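"""SLIC superpixels, implemented from scratch.

The clustering is a localized k-means over joint (color, position) features:

1. Seeds are placed on a regular grid with step S = sqrt(N·N/K) on an N×N
   image (grid spacing ⌊S⌋, offset ⌊S/2⌋ from the border), so the realized
   seed count K′ = ⌊N/⌊S⌋⌋² may differ slightly from the request K.
2. Each seed is nudged to the minimum-gradient pixel in its n×n (n=3)
   neighborhood, so no seed sits on an edge.
3. Each seed scans only a 2S×2S window around itself; every pixel takes the
   label of the seed minimizing D′ = sqrt((d_c/m)² + (d_s/S)²), where d_c is
   the Euclidean color distance (CIELAB by default), d_s the Euclidean
   spatial distance, and m the compactness weight.
4. Seeds move to the mean position/color of their members; steps 3-4 repeat
   for ``n_iters`` rounds (early exit once no label changes).
5. Labels are relabeled to consecutive ids; optionally, connected-component
   fragments that lost their seed are merged into the largest adjacent block.

The procedure contains no randomness: identical inputs give identical
labelings, with argmin ties always resolved toward the lowest seed id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.measure import label as cc_label

from .io_formats import RAW8BIT, RgbImage


@dataclass
class SlicParams:
    """Knobs of the superpixel stage.

    K is the requested number of superpixels; m trades color fidelity
    against spatial compactness (default 10 on the CIELAB scale).
    """

    K: int = 200
    m: float = 10.0
    n_iters: int = 10
    perturb_window: int = 3
    enforce_connectivity: bool = True
    color_space: str = "lab"  # or "rgb" for ablation

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.perturb_window % 2 != 1:
            raise ValueError("perturb_window must be odd")
        if self.color_space not in ("lab", "rgb"):
            raise ValueError("color_space must be 'lab' or 'rgb'")


@dataclass
class SeedPoint:
    position: tuple  # (row, col) floats
    color: np.ndarray  # feature vector in the working color space


@dataclass
class SuperpixelLabeling:
    """A partition of the pixel grid into K′ blocks labeled 0..K′−1."""

    labels: np.ndarray
    n_blocks: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.min() < 0 or self.labels.max() >= self.n_blocks:
            raise ValueError("labels must lie in [0, n_blocks)")

    @property
    def shape(self):
        return self.labels.shape

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_blocks)

    def block_index(self) -> dict:
        """block id → (rows, cols) arrays of member pixels."""
        order = np.argsort(self.labels.ravel(), kind="stable")
        flat = self.labels.ravel()[order]
        bounds = np.searchsorted(flat, np.arange(self.n_blocks + 1))
        h, w = self.labels.shape
        rows, cols = np.divmod(order, w)
        return {
            b: (rows[bounds[b] : bounds[b + 1]], cols[bounds[b] : bounds[b + 1]])
            for b in range(self.n_blocks)
        }


# ---------------------------------------------------------------------------
# steps


def init_seeds(side: int, K: int, features: np.ndarray | None = None):
    """Step 1: regular-grid seeds. Returns (S, seeds).

    S = sqrt(side²/K); seeds sit every ⌊S⌋ pixels starting ⌊S/2⌋ from the
    border. ``features`` (side×side×C) supplies seed colors; without it the
    colors are zero vectors.
    """
    if side < 2:
        raise ValueError("image side must be >= 2")
    if not 1 <= K <= side * side:
        raise ValueError(f"K must lie in [1, {side * side}]")
    S = float(np.sqrt(side * side / K))
    step = int(np.floor(S))
    if step < 1:
        raise ValueError("K too large: seed spacing collapsed below one pixel")
    off = step // 2
    coords = np.arange(off, off + step * (side // step), step)
    coords = coords[coords < side]
    seeds = []
    for r in coords:
        for c in coords:
            color = (
                features[r, c].astype(float)
                if features is not None
                else np.zeros(3)
            )
            seeds.append(SeedPoint((float(r), float(c)), color))
    return S, seeds


def _gradient_map(features: np.ndarray) -> np.ndarray:
    """Sum over channels of squared central differences (edge-padded)."""
    fp = np.pad(features, ((1, 1), (1, 1), (0, 0)), mode="edge")
    gx = fp[1:-1, 2:] - fp[1:-1, :-2]
    gy = fp[2:, 1:-1] - fp[:-2, 1:-1]
    return (gx**2 + gy**2).sum(axis=2)


def perturb_seeds(features: np.ndarray, seeds: list, n: int = 3) -> list:
    """Step 2: move each seed to the min-gradient pixel in its n×n window.

    Ties keep the original position if it attains the minimum, otherwise the
    first (row-major) minimizer wins — deterministic either way.
    """
    if n % 2 != 1:
        raise ValueError("window size n must be odd")
    grad = _gradient_map(features)
    h, w = grad.shape
    half = n // 2
    out = []
    for seed in seeds:
        r0, c0 = int(round(seed.position[0])), int(round(seed.position[1]))
        rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
        window = grad[rlo:rhi, clo:chi]
        gmin = window.min()
        if grad[r0, c0] <= gmin:
            r, c = r0, c0
        else:
            k = int(np.argmin(window))
            r = rlo + k // window.shape[1]
            c = clo + k % window.shape[1]
        out.append(SeedPoint((float(r), float(c)), features[r, c].astype(float)))
    return out


def assign_pixels(
    features: np.ndarray, seeds: list, S: float, m: float
) -> SuperpixelLabeling:
    """Step 3: windowed nearest-seed assignment under D′.

    Each seed claims pixels within a 2S×2S window centered on it; a pixel
    covered by several windows takes the seed with the smallest
    D′ = sqrt((d_c/m)² + (d_s/S)²) (lowest seed id on ties). Pixels outside
    every window fall back to a global nearest-seed pass.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    h, w = features.shape[:2]
    best = np.full((h, w), np.inf)
    labels = np.full((h, w), -1, dtype=np.int32)
    half = int(round(S))
    for sid, seed in enumerate(seeds):
        sr, sc = seed.position
        rlo, rhi = max(0, int(np.floor(sr)) - half), min(h, int(np.ceil(sr)) + half + 1)
        clo, chi = max(0, int(np.floor(sc)) - half), min(w, int(np.ceil(sc)) + half + 1)
        patch = features[rlo:rhi, clo:chi]
        dc2 = ((patch - seed.color) ** 2).sum(axis=2)
        rr = np.arange(rlo, rhi)[:, None] - sr
        cc = np.arange(clo, chi)[None, :] - sc
        ds2 = rr**2 + cc**2
        d2 = dc2 / (m * m) + ds2 / (S * S)
        win_best = best[rlo:rhi, clo:chi]
        better = d2 < win_best  # strict: earlier (lower) seed id wins ties
        win_best[better] = d2[better]
        labels[rlo:rhi, clo:chi][better] = sid
    uncovered = labels < 0
    if uncovered.any():
        rows, cols = np.nonzero(uncovered)
        feats = features[rows, cols]
        d_best = np.full(rows.shape, np.inf)
        l_best = np.zeros(rows.shape, dtype=np.int32)
        for sid, seed in enumerate(seeds):
            dc2 = ((feats - seed.color) ** 2).sum(axis=1)
            ds2 = (rows - seed.position[0]) ** 2 + (cols - seed.position[1]) ** 2
            d2 = dc2 / (m * m) + ds2 / (S * S)
            better = d2 < d_best
            d_best[better] = d2[better]
            l_best[better] = sid
        labels[rows, cols] = l_best
    return SuperpixelLabeling(labels, len(seeds))


def update_seeds(labeling: SuperpixelLabeling, features: np.ndarray, seeds: list) -> list:
    """Step 4: move each seed to the centroid (position and color) of its
    block; empty blocks keep their previous seed."""
    lab = labeling.labels
    h, w = lab.shape
    k = labeling.n_blocks
    counts = np.bincount(lab.ravel(), minlength=k).astype(float)
    rows = np.repeat(np.arange(h), w).astype(float)
    cols = np.tile(np.arange(w), h).astype(float)
    sum_r = np.bincount(lab.ravel(), weights=rows, minlength=k)
    sum_c = np.bincount(lab.ravel(), weights=cols, minlength=k)
    flat_feats = features.reshape(-1, features.shape[2])
    sum_feat = np.stack(
        [
            np.bincount(lab.ravel(), weights=flat_feats[:, ch], minlength=k)
            for ch in range(flat_feats.shape[1])
        ],
        axis=1,
    )  # (k, C)
    out = []
    for b in range(k):
        if counts[b] == 0:
            out.append(seeds[b])
            continue
        out.append(
            SeedPoint(
                (sum_r[b] / counts[b], sum_c[b] / counts[b]), sum_feat[b] / counts[b]
            )
        )
    return out


def _to_features(img: RgbImage, color_space: str) -> np.ndarray:
    px = img.pixels
    if img.value_range != RAW8BIT:
        px = np.clip((px + 1.0) * 127.5, 0, 255)
    px = px.astype(np.float64)
    if color_space == "lab":
        return rgb2lab(px / 255.0)
    return px


def _enforce_connectivity(labeling: SuperpixelLabeling, seeds: list) -> np.ndarray:
    """Step 5 cleanup: keep, per block, the connected component containing
    its seed (falling back to its largest component if the seed was lost);
    merge every orphan fragment into the adjacent block with which it
    shares the longest boundary."""
    lab = labeling.labels
    h, w = lab.shape
    # background=-1: label id 0 is a real block, not background
    comp = cc_label(lab, connectivity=1, background=-1)
    ncomp = int(comp.max())
    flat_comp, flat_lab = comp.ravel(), lab.ravel()
    comp_sizes = np.bincount(flat_comp, minlength=ncomp + 1)
    # block id of each component (any member pixel works: comps are label-pure)
    first_pix = np.zeros(ncomp + 1, dtype=np.int64)
    first_pix[flat_comp[::-1]] = np.arange(flat_comp.size - 1, -1, -1)
    comp_block = flat_lab[first_pix]

    keep = np.full(labeling.n_blocks, -1, dtype=np.int64)
    for b, seed in enumerate(seeds[: labeling.n_blocks]):
        sr = min(max(int(round(seed.position[0])), 0), h - 1)
        sc = min(max(int(round(seed.position[1])), 0), w - 1)
        if lab[sr, sc] == b:
            keep[b] = comp[sr, sc]
    seedless = keep < 0
    for ci in range(1, ncomp + 1):  # fallback: largest component of the block
        b = comp_block[ci]
        if seedless[b] and (keep[b] < 0 or comp_sizes[ci] > comp_sizes[keep[b]]):
            keep[b] = ci

    # component adjacency, with multiplicity = shared boundary length
    pairs = []
    for a, bb in (
        (comp[:, :-1], comp[:, 1:]),
        (comp[:-1, :], comp[1:, :]),
    ):
        diff = a != bb
        pairs.append(np.stack([a[diff], bb[diff]], axis=1))
    pairs = np.concatenate(pairs)
    pairs = np.concatenate([pairs, pairs[:, ::-1]])
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    adj_start = np.searchsorted(pairs[:, 0], np.arange(ncomp + 2))

    comp_assign = comp_block.astype(np.int64).copy()
    for ci in range(1, ncomp + 1):
        b = comp_block[ci]
        if keep[b] == ci:
            continue  # the canonical fragment stays put
        neigh = pairs[adj_start[ci] : adj_start[ci + 1], 1]
        if neigh.size == 0:
            continue
        # merge into the adjacent block sharing the longest boundary with
        # the fragment: merging by block area was found to swallow fragments
        # across color boundaries, which defeats the refinement stage
        cand_blocks = comp_assign[neigh]
        cand_blocks = cand_blocks[cand_blocks != b]
        if cand_blocks.size == 0:
            continue
        counts = np.bincount(cand_blocks)
        comp_assign[ci] = int(np.argmax(counts))  # ties: lowest block id
    return comp_assign[comp].astype(np.int32)


def _relabel_consecutive(lab: np.ndarray):
    ids = np.unique(lab)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(ids.size)
    return remap[lab], ids.size


def slic(img: RgbImage, params: SlicParams | None = None) -> SuperpixelLabeling:
    """Full SLIC pipeline on a square image: steps 1-5."""
    params = params or SlicParams()
    if img.height != img.width:
        raise ValueError("slic expects a square image; resize to canonical first")
    features = _to_features(img, params.color_space)
    S, seeds = init_seeds(img.height, params.K, features)
    seeds = perturb_seeds(features, seeds, params.perturb_window)
    labeling = None
    prev = None
    for _ in range(params.n_iters):
        labeling = assign_pixels(features, seeds, S, params.m)
        if prev is not None and np.array_equal(prev, labeling.labels):
            break
        prev = labeling.labels
        seeds = update_seeds(labeling, features, seeds)
    lab = labeling.labels
    if params.enforce_connectivity:
        # one pass can strand fragments whose neighbor fragment also moved;
        # repeat until the component count stops shrinking
        for _ in range(5):
            merged = _enforce_connectivity(
                SuperpixelLabeling(lab, labeling.n_blocks), seeds
            )
            if np.array_equal(merged, lab):
                break
            lab = merged
    lab, k = _relabel_consecutive(lab)
    return SuperpixelLabeling(lab, k)


def save_labeling(
    labeling: SuperpixelLabeling, path, params: SlicParams | None = None
) -> None:
    """Write block ids as a 16-bit single-channel PNG plus a JSON sidecar
    (requested K, realized K′, parameters) at ``<path>.json``."""
    import json
    from pathlib import Path

    from PIL import Image

    if labeling.n_blocks > 2**16:
        raise ValueError("more than 2^16 blocks cannot be stored as 16-bit PNG")
    Image.fromarray(labeling.labels.astype(np.uint16), mode="I;16").save(path)
    sidecar = {"n_blocks": int(labeling.n_blocks)}
    if params is not None:
        sidecar.update(
            K_requested=params.K, m=params.m, n_iters=params.n_iters,
            enforce_connectivity=params.enforce_connectivity,
            color_space=params.color_space,
        )
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_labeling(path) -> SuperpixelLabeling:
    """Inverse of :func:`save_labeling` (the sidecar is optional)."""
    import json
    from pathlib import Path

    from PIL import Image

    with Image.open(path) as im:
        labels = np.asarray(im, dtype=np.int32)
    sidecar = Path(str(path) + ".json")
    n_blocks = (
        json.loads(sidecar.read_text())["n_blocks"]
        if sidecar.exists()
        else int(labels.max()) + 1
    )
    return SuperpixelLabeling(labels, n_blocks)


def boundary_overlay(img: RgbImage, labeling: SuperpixelLabeling) -> RgbImage:
    """Paint block boundaries yellow on a copy of the image (visual check)."""
    px = img.pixels.copy()
    if img.value_range != RAW8BIT:
        px = np.clip((px + 1.0) * 127.5, 0, 255).astype(np.uint8)
    lab = labeling.labels
    edge = np.zeros(lab.shape, dtype=bool)
    edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
    edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    px[edge] = (255, 255, 0)
    return RgbImage(px, RAW8BIT)
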