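"""Image loading, grayscale conversion and automatic H&E orientation.

Both modalities are handled as 8-bit grayscale grids: the DAPI morphology
image is bright-nuclei-on-dark, and the H&E image is converted to inverted
luminance so that its nuclei are bright too.  The H&E scan may be rotated
or flipped relative to the instrument's morphology image; the orientation
is recovered by exhaustive search over the 8 axis-aligned symmetries
(4 rotations x optional horizontal mirror), scoring each candidate by the
mean square error between downsampled thumbnails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A 2-D intensity grid.

    ``pixels`` is row-major: row index is y (along the image length),
    column index is x (along the width).  Intensities live in
    ``[0, max_value]`` with ``max_value`` = 255 throughout the pipeline.
    """

    pixels: np.ndarray
    max_value: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError(
                f"intensities must lie in [0, {self.max_value}]"
            )

    @property
    def width(self) -> int:
        """W: number of columns (x extent)."""
        return self.pixels.shape[1]

    @property
    def length(self) -> int:
        """L: number of rows (y extent)."""
        return self.pixels.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        """(W, L)."""
        return (self.width, self.length)


@dataclass(frozen=True)
class OrientationCode:
    """One of the 8 discrete image orientations.

    ``mirrored`` means a horizontal flip applied before the counter-clockwise
    rotation by ``rotation`` degrees.
    """

    rotation: int = 0
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")


ALL_ORIENTATIONS: tuple[OrientationCode, ...] = tuple(
    OrientationCode(rot, mir) for mir in (False, True) for rot in (0, 90, 180, 270)
)


def apply_orientation(arr: np.ndarray, code: OrientationCode) -> np.ndarray:
    """Apply an orientation to a 2-D (or HxWxC) array: mirror, then rotate CCW."""
    out = np.asarray(arr)
    if code.mirrored:
        out = out[:, ::-1]
    k = code.rotation // 90
    if k:
        out = np.rot90(out, k=k, axes=(0, 1))
    return np.ascontiguousarray(out)


def invert_orientation(code: OrientationCode) -> OrientationCode:
    """Group inverse of an orientation.

    Mirrored orientations are reflections and therefore involutions; pure
    rotations invert by negating the angle.
    """
    if code.mirrored:
        return code
    return OrientationCode((360 - code.rotation) % 360, False)


def orient_point(
    point: tuple[float, float], code: OrientationCode, dims: tuple[int, int]
) -> tuple[float, float]:
    """Map a pixel coordinate through :func:`apply_orientation`.

    ``dims`` is (W, L) of the image *before* the orientation is applied.
    Returns the coordinate of the same pixel in the oriented image.
    """
    x, y = point
    w, l = dims
    if code.mirrored:
        x = (w - 1) - x
    for _ in range(code.rotation // 90):
        # one CCW quarter turn: (x, y) -> (y, W-1-x); dims (W, L) -> (L, W)
        x, y = y, (w - 1) - x
        w, l = l, w
    return (x, y)


def oriented_dims(dims: tuple[int, int], code: OrientationCode) -> tuple[int, int]:
    """(W, L) after applying ``code`` to an image of dims (W, L)."""
    if code.rotation in (90, 270):
        return (dims[1], dims[0])
    return dims


def _rescale_to_uint8_range(plane: np.ndarray) -> np.ndarray:
    """8-bit data passes through; deeper planes are min-max stretched."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if 0 <= lo and hi <= 255:
        return plane
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) * (255.0 / (hi - lo))


def load_gray_image(
    path: str | Path,
    channel_policy: str = "first_plane",
    pyramid_level: int = 0,
) -> GrayImage:
    """Load a raster file as an 8-bit grayscale image.

    TIFF/OME-TIFF files are read with tifffile (``pyramid_level`` selects the
    pyramid series level); PNG/JPEG go through imageio.  RGB inputs are
    reduced by ``channel_policy``: ``first_plane`` keeps channel 0,
    ``luminance`` applies BT.601 weights.  Planes deeper than 8 bit are
    min-max stretched to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                if series.is_pyramidal and pyramid_level < len(series.levels):
                    arr = series.levels[pyramid_level].asarray()
                else:
                    arr = series.asarray()
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - delegated to readers
        raise IOError(f"could not read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = np.squeeze(arr)
    if arr.ndim == 3:
        # channel axis may be first (CYX planes) or last (YXC rasters)
        if arr.shape[-1] in (3, 4):
            rgb = arr[..., :3].astype(np.float64)
            if channel_policy == "luminance":
                arr = rgb @ _LUMA
            else:
                arr = rgb[..., 0]
        else:
            arr = arr[0]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return GrayImage(_rescale_to_uint8_range(arr))


def to_grayscale_inverted(he_rgb: np.ndarray) -> GrayImage:
    """Convert an RGB H&E raster to inverted luminance.

    H&E nuclei are dark on a light background; inverting the luminance
    (255 - Y) makes them bright-on-dark, directly comparable to DAPI.
    """
    arr = np.asarray(he_rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError("expected an RGB raster with 3 (or 4) channels")
    lum = arr[..., :3] @ _LUMA
    return GrayImage(np.clip(255.0 - lum, 0.0, 255.0))


def mse(a: GrayImage | np.ndarray, b: GrayImage | np.ndarray) -> float:
    """Mean square error between two equal-shaped intensity grids."""
    pa = a.pixels if isinstance(a, GrayImage) else np.asarray(a, dtype=np.float64)
    pb = b.pixels if isinstance(b, GrayImage) else np.asarray(b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    d = pa - pb
    return float(np.mean(d * d))


def resize_bilinear(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving the intensity range (no anti-alias filter)."""
    return _sk_resize(
        np.asarray(arr, dtype=np.float64),
        shape,
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )


def auto_orient_he(
    he: GrayImage,
    dapi: GrayImage,
    thumbnail_side: int = 512,
    candidates: tuple[OrientationCode, ...] = ALL_ORIENTATIONS,
) -> tuple[GrayImage, OrientationCode, dict[OrientationCode, float]]:
    """Recover the orientation of the H&E image relative to the DAPI layout.

    ``he`` must already be the inverted-luminance grayscale of the H&E scan.
    Every candidate correction is applied, both images are resized to a
    square thumbnail, and the candidate minimizing the thumbnail MSE wins
    (ties broken toward identity by scanning identity first with a strict
    improvement rule).

    Returns ``(corrected H&E at full resolution, applied orientation, mse
    table keyed by the candidate correction)``.  The reported orientation is
    the one that appears to have been applied to the H&E scan, i.e. the
    inverse of the winning correction.
    """
    if thumbnail_side < 16:
        raise ValueError("thumbnail_side must be >= 16")
    dapi_thumb = resize_bilinear(dapi.pixels, (thumbnail_side, thumbnail_side))
    # identity first so ties break toward it
    ordered = sorted(candidates, key=lambda c: (c != OrientationCode(0, False)))
    table: dict[OrientationCode, float] = {}
    best_code: OrientationCode | None = None
    best_mse = np.inf
    for corr in ordered:
        oriented = apply_orientation(he.pixels, corr)
        thumb = resize_bilinear(oriented, (thumbnail_side, thumbnail_side))
        score = mse(thumb, dapi_thumb)
        table[corr] = score
        if score < best_mse:
            best_mse = score
            best_code = corr
    assert best_code is not None
    corrected = GrayImage(apply_orientation(he.pixels, best_code), he.max_value)
    applied = invert_orientation(best_code)
    logger.debug("auto-orientation: applied=%s (thumbnail MSE %.3f)", applied, best_mse)
    return corrected, applied, table
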