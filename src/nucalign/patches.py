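"""Multi-directional PSNR patch matching.

Each sampled H&E nucleus center is mapped into the DAPI image by image-size
proportionality, a square search region collects candidate DAPI nuclei, and
five square patches (center plus up/down/left/right displacements) are
cropped around both the H&E nucleus and every candidate.  Candidates are
ranked per direction by PSNR between the H&E segmentation rendering and the
contrast-stretched DAPI patch; a correspondence is kept only when the same
candidate tops all five rankings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .images import GrayImage, mse, resize_bilinear
from .segmentation import NucleusRecord, SegmentationResult

logger = logging.getLogger(__name__)

DIRECTIONS = ("center", "up", "down", "left", "right")


def map_center(
    he_point: tuple[float, float],
    he_dims: tuple[int, int],
    dapi_dims: tuple[int, int],
) -> tuple[float, float]:
    """Map an H&E coordinate into the DAPI image by size proportionality.

    X_DAPI = W_DAPI * X_HE / W_HE and Y_DAPI = L_DAPI * Y_HE / L_HE,
    real-valued (no rounding).
    """
    (wh, lh), (wd, ld) = he_dims, dapi_dims
    if min(wh, lh, wd, ld) <= 0:
        raise ValueError("image dimensions must be strictly positive")
    x, y = he_point
    if not (0 <= x <= wh and 0 <= y <= lh):
        raise ValueError(f"point {he_point} outside H&E bounds {he_dims}")
    return (wd * x / wh, ld * y / lh)


@dataclass
class SearchRegion:
    """A square region of the DAPI image holding candidate nuclei."""

    center: tuple[float, float]
    radius: float
    member_ids: list


def build_search_region(
    dapi_center: tuple[float, float],
    ratio: float,
    dapi_image_dims: tuple[int, int],
    dapi_nuclei: list[NucleusRecord],
    min_cells: int = 50,
) -> SearchRegion | None:
    """Collect DAPI nuclei within a square of half-side ratio * min(W, L).

    Returns ``None`` (a rejection, not an error) when fewer than
    ``min_cells`` nucleus centers fall inside the square.
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must lie in (0, 1]")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    radius = ratio * min(dapi_image_dims)
    cx, cy = dapi_center
    members = [
        rec.id
        for rec in dapi_nuclei
        if abs(rec.center[0] - cx) <= radius and abs(rec.center[1] - cy) <= radius
    ]
    if len(members) < min_cells:
        return None
    return SearchRegion((cx, cy), radius, members)


def _as_xy_pair(value) -> tuple[int, int]:
    if np.isscalar(value):
        return (int(value), int(value))
    vx, vy = value
    return (int(vx), int(vy))


def crop_directional_patches(
    image: GrayImage | np.ndarray,
    center: tuple[float, float],
    crop_radius: int | tuple[int, int],
    move_distance: int | tuple[int, int],
    patch_size: int = 224,
) -> dict[str, np.ndarray] | None:
    """Crop five square patches around a center and resize each to patch_size.

    Crop windows are half-open, ``[c - r, c + r)`` per axis (side 2r).  The
    four directional crops displace the center by the move distance along
    one axis (up = decreasing y).  Returns ``None`` when any window would
    extend past the image bounds; patches near the border are skipped rather
    than padded so that PSNR never sees synthetic fill.

    ``crop_radius`` and ``move_distance`` accept (rx, ry) pairs so that the
    H&E side can use per-axis values matched to its pixel scale.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    rx, ry = _as_xy_pair(crop_radius)
    mx, my = _as_xy_pair(move_distance)
    if rx <= 0 or ry <= 0:
        raise ValueError("crop_radius must be positive")
    if mx < 0 or my < 0:
        raise ValueError("move_distance must be non-negative")
    length, width = pixels.shape[:2]
    cx, cy = int(round(center[0])), int(round(center[1]))
    centers = {
        "center": (cx, cy),
        "up": (cx, cy - my),
        "down": (cx, cy + my),
        "left": (cx - mx, cy),
        "right": (cx + mx, cy),
    }
    patches: dict[str, np.ndarray] = {}
    for name, (px, py) in centers.items():
        x0, x1 = px - rx, px + rx
        y0, y1 = py - ry, py + ry
        if x0 < 0 or y0 < 0 or x1 > width or y1 > length:
            return None
        patches[name] = resize_bilinear(pixels[y0:y1, x0:x1], (patch_size, patch_size))
    return patches


def psnr(a: GrayImage | np.ndarray, b: GrayImage | np.ndarray, L: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(L^2 / MSE) in dB.

    Identical images have zero MSE; the limit is reported as ``math.inf``,
    which ranks above every finite PSNR.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    m = mse(a, b)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(L * L / m)


def stretch_contrast(patch: np.ndarray, max_value: float = 255.0) -> np.ndarray:
    """Min-max stretch a patch to [0, max_value]; constant patches map to 0."""
    patch = np.asarray(patch, dtype=np.float64)
    lo, hi = patch.min(), patch.max()
    if hi == lo:
        return np.zeros_like(patch)
    return (patch - lo) * (max_value / (hi - lo))


def render_binary_labels(seg: SegmentationResult) -> GrayImage:
    """Render a label image as a binary mask: nucleus pixels 255, background 0."""
    return GrayImage((seg.label_image > 0).astype(np.float64) * 255.0)


def render_he_patch_for_psnr(
    seg: SegmentationResult,
    center: tuple[float, float],
    crop_radius: int | tuple[int, int],
    move_distance: int | tuple[int, int],
    patch_size: int = 224,
) -> dict[str, np.ndarray] | None:
    """Directional patches cropped from the binary rendering of a segmentation."""
    return crop_directional_patches(
        render_binary_labels(seg), center, crop_radius, move_distance, patch_size
    )


@dataclass
class MatchCandidate:
    """A putative H&E <-> DAPI nucleus correspondence.

    ``psnr_by_direction`` holds, per moving direction, the maximum PSNR over
    all candidates in the search region; ``consensus`` is true iff the same
    DAPI nucleus attains that maximum in all five directions.
    """

    he_id: int | str
    dapi_id: int | str
    psnr_by_direction: dict[str, float] = field(default_factory=dict)
    consensus: bool = False


def consensus_match(
    he_patches: dict[str, np.ndarray],
    he_id: int | str,
    region: SearchRegion,
    dapi_image: GrayImage,
    dapi_nuclei_by_id: dict,
    crop_radius: int | tuple[int, int],
    move_distance: int | tuple[int, int],
    patch_size: int = 224,
    L: float = 255.0,
    patch_cache: dict | None = None,
) -> MatchCandidate | None:
    """Five-direction top-1 consensus over the candidates of a search region.

    Every candidate's patches are cropped around its own center with the
    same radius/move scheme, contrast-stretched to [0, L], and compared to
    the H&E patches by PSNR.  Candidates whose crops cross the image bounds
    are excluded.  Argmax ties break toward the smallest candidate id.
    Returns the consensus correspondence, or ``None`` when the five
    direction-wise winners disagree.
    """
    best_id: dict[str, int | str | None] = {d: None for d in DIRECTIONS}
    best_psnr: dict[str, float] = {d: -math.inf for d in DIRECTIONS}
    for cand_id in sorted(region.member_ids, key=str):
        rec = dapi_nuclei_by_id[cand_id]
        if patch_cache is not None and cand_id in patch_cache:
            cand_patches = patch_cache[cand_id]
        else:
            cand_patches = crop_directional_patches(
                dapi_image, rec.center, crop_radius, move_distance, patch_size
            )
            if cand_patches is not None:
                cand_patches = {
                    d: stretch_contrast(p, L) for d, p in cand_patches.items()
                }
            if patch_cache is not None:
                patch_cache[cand_id] = cand_patches
        if cand_patches is None:
            continue
        for d in DIRECTIONS:
            score = psnr(he_patches[d], cand_patches[d], L)
            if score > best_psnr[d]:
                best_psnr[d] = score
                best_id[d] = cand_id
    winners = {best_id[d] for d in DIRECTIONS}
    if len(winners) != 1 or None in winners:
        return None
    (winner,) = winners
    return MatchCandidate(
        he_id=he_id,
        dapi_id=winner,
        psnr_by_direction=dict(best_psnr),
        consensus=True,
    )
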