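"""Synthetic paired-scene generator (fully synthetic test data).

A planted layout of elliptical nuclei is rendered twice: once as a
DAPI-like grayscale image (bright ellipses on a dark background with
additive Gaussian noise) and once as an H&E-like RGB raster (dark purple
ellipses on a light background) at an independently chosen pixel scale,
with a known discrete orientation applied afterwards.  The generator also
emits the DAPI boundary-polygon table, an H&E-frame ground-truth label
image standing in for segmentation, and the planted correspondence list —
everything the pipeline consumes, with a closed-form oracle transform for
scoring its output.  Real-data features such as staining artifacts, tissue
folds and out-of-focus regions are deliberately not simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile
from skimage.draw import polygon as _draw_polygon

from .images import GrayImage, OrientationCode, apply_orientation, invert_orientation, orient_point, oriented_dims

logger = logging.getLogger(__name__)

N_BOUNDARY_VERTICES = 24


@dataclass
class SceneSpec:
    """Parameters of a planted paired scene.

    Dims are (W, L).  ``orientation`` is applied to the H&E render (and the
    label image) after rasterization; ``min_center_spacing`` is enforced
    pairwise between planted centers in DAPI coordinates.
    """

    n_nuclei: int = 400
    dapi_dims: tuple[int, int] = (600, 900)
    he_dims: tuple[int, int] = (600, 900)
    orientation: OrientationCode = field(default_factory=OrientationCode)
    nucleus_radius_range: tuple[float, float] = (4.0, 8.0)
    intensity_noise_sd: float = 6.0
    seed: int = 0
    min_center_spacing: float = 24.0
    #: fraction of extra nuclei rendered in only one modality (half DAPI-only,
    #: half H&E-only); they have no planted counterpart.
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ValueError("decoy_fraction must lie in [0, 1]")
        if min(self.dapi_dims) < 32 or min(self.he_dims) < 32:
            raise ValueError("scene dimensions must be at least 32 px")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid nucleus_radius_range")


@dataclass
class Scene:
    """A generated paired scene with its ground truth."""

    spec: SceneSpec
    dapi: GrayImage
    he_rgb: np.ndarray  # fixture H&E, orientation applied, uint8 HxWx3
    boundary_table: pd.DataFrame  # cell_id, vertex_x, vertex_y (DAPI coords)
    label_image: np.ndarray  # H&E fixture frame, int32
    correspondences: pd.DataFrame  # he_label, dapi_id, centers both frames


def _place_centers(
    rng: np.random.Generator, spec: SceneSpec, n_total: int
) -> np.ndarray:
    """Dart-throwing placement with a spacing grid; raises when jammed."""
    w, l = spec.dapi_dims
    margin = spec.nucleus_radius_range[1] + 2.0
    spacing = spec.min_center_spacing
    cell = max(spacing, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    centers: list[tuple[float, float]] = []
    max_tries = 400 * max(n_total, 1)
    tries = 0
    while len(centers) < n_total:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_total} nuclei at spacing "
                f"{spacing} in {spec.dapi_dims}; reduce n_nuclei or spacing"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, l - margin)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for k in grid.get((gx + dx, gy + dy), ()):
                    px, py = centers[k]
                    if (px - x) ** 2 + (py - y) ** 2 < spacing**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(centers))
            centers.append((x, y))
    return np.array(centers, dtype=np.float64).reshape(-1, 2)


def _ellipse_polygon(
    cx: float, cy: float, a: float, b: float, theta: float, n: int = N_BOUNDARY_VERTICES
) -> np.ndarray:
    """(n, 2) polygon of an ellipse with semi-axes a, b rotated by theta."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    x = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    y = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.column_stack([x, y])


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a planted nucleus layout into a fully paired test scene."""
    rng = np.random.default_rng(spec.seed)
    wd, ld = spec.dapi_dims
    wh, lh = spec.he_dims
    sx, sy = wh / wd, lh / ld

    n_decoys = round(spec.decoy_fraction * spec.n_nuclei)
    n_dapi_only = n_decoys - n_decoys // 2
    n_total = spec.n_nuclei + n_decoys
    centers = _place_centers(rng, spec, n_total)
    lo, hi = spec.nucleus_radius_range
    axes = rng.uniform(lo, hi, size=(n_total, 2))
    thetas = rng.uniform(0.0, np.pi, size=n_total)
    dapi_fill = rng.uniform(190.0, 250.0, size=n_total)

    dapi = np.full((ld, wd), 10.0)
    he = np.empty((lh, wh, 3), dtype=np.float64)
    he[..., 0] = 232.0
    he[..., 1] = 228.0
    he[..., 2] = 238.0
    labels = np.zeros((lh, wh), dtype=np.int32)

    rows = []
    corr = []
    for k in range(n_total):
        shared = k < spec.n_nuclei
        in_dapi = shared or k < spec.n_nuclei + n_dapi_only
        in_he = shared or k >= spec.n_nuclei + n_dapi_only
        cx, cy = centers[k]
        poly = _ellipse_polygon(cx, cy, axes[k, 0], axes[k, 1], thetas[k])
        purple = np.array([95.0, 60.0, 140.0]) + rng.uniform(-15.0, 15.0, size=3)

        if in_dapi:
            dapi_id = f"nuc-{k + 1:05d}"
            for vx, vy in poly:
                rows.append((dapi_id, vx, vy))
            rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=dapi.shape)
            dapi[rr, cc] = dapi_fill[k]
        if in_he:
            he_poly = poly * np.array([sx, sy])
            rr, cc = _draw_polygon(he_poly[:, 1], he_poly[:, 0], shape=labels.shape)
            labels[rr, cc] = k + 1
            he[rr, cc] = purple

        if shared:
            he_center_aligned = (cx * sx, cy * sy)
            he_center_fixture = orient_point(
                he_center_aligned, spec.orientation, (wh, lh)
            )
            corr.append(
                {
                    "he_label": k + 1,
                    "dapi_id": dapi_id,
                    "dapi_x": cx,
                    "dapi_y": cy,
                    "he_x_aligned": he_center_aligned[0],
                    "he_y_aligned": he_center_aligned[1],
                    "he_x_fixture": he_center_fixture[0],
                    "he_y_fixture": he_center_fixture[1],
                }
            )

    if spec.intensity_noise_sd > 0:
        dapi += rng.normal(0.0, spec.intensity_noise_sd, size=dapi.shape)
        he += rng.normal(0.0, spec.intensity_noise_sd, size=he.shape)
    dapi = np.clip(dapi, 0.0, 255.0)
    he = np.clip(he, 0.0, 255.0)

    he_fixture = apply_orientation(he, spec.orientation).astype(np.uint8)
    labels_fixture = apply_orientation(labels, spec.orientation)

    boundary_table = pd.DataFrame(rows, columns=["cell_id", "vertex_x", "vertex_y"])
    correspondences = pd.DataFrame(
        corr,
        columns=[
            "he_label",
            "dapi_id",
            "dapi_x",
            "dapi_y",
            "he_x_aligned",
            "he_y_aligned",
            "he_x_fixture",
            "he_y_fixture",
        ],
    )
    return Scene(
        spec=spec,
        dapi=GrayImage(dapi),
        he_rgb=he_fixture,
        boundary_table=boundary_table,
        label_image=labels_fixture,
        correspondences=correspondences,
    )


def planted_transform(spec: SceneSpec):
    """Closed-form oracle mapping fixture H&E coordinates to DAPI coordinates.

    The inverse of the planted orientation is applied first (a pure
    coordinate permutation), then the per-axis scale factors map the
    aligned H&E frame onto the DAPI pixel grid.
    """
    wh, lh = spec.he_dims
    wd, ld = spec.dapi_dims
    fixture_dims = oriented_dims((wh, lh), spec.orientation)
    inverse = invert_orientation(spec.orientation)

    def transform(x: float, y: float) -> tuple[float, float]:
        ax, ay = orient_point((x, y), inverse, fixture_dims)
        return (ax * wd / wh, ay * ld / lh)

    return transform


def write_scene(scene: Scene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene in the dialects the real pipeline reads.

    DAPI as OME-TIFF, H&E as PNG, boundaries and correspondences as CSV,
    labels as TIFF, plus a JSON scene description.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dapi": out / "morphology.ome.tif",
        "he": out / "he_image.png",
        "boundaries": out / "nucleus_boundaries.csv",
        "labels": out / "he_labels.tif",
        "correspondences": out / "correspondences.csv",
        "spec": out / "scene.json",
    }
    # pinned UUID keeps the OME-XML (and hence the file bytes) deterministic
    tifffile.imwrite(
        paths["dapi"],
        scene.dapi.pixels.astype(np.uint8),
        ome=True,
        metadata={
            "UUID": "urn:uuid:00000000-0000-0000-0000-000000000000",
            "Creator": "nucalign",
        },
    )
    iio.imwrite(paths["he"], scene.he_rgb)
    scene.boundary_table.to_csv(paths["boundaries"], index=False)
    tifffile.imwrite(paths["labels"], scene.label_image.astype(np.int32))
    scene.correspondences.to_csv(paths["correspondences"], index=False)
    spec = scene.spec
    paths["spec"].write_text(
        json.dumps(
            {
                "n_nuclei": spec.n_nuclei,
                "dapi_dims": list(spec.dapi_dims),
                "he_dims": list(spec.he_dims),
                "orientation": {
                    "rotation": spec.orientation.rotation,
                    "mirrored": spec.orientation.mirrored,
                },
                "nucleus_radius_range": list(spec.nucleus_radius_range),
                "intensity_noise_sd": spec.intensity_noise_sd,
                "seed": spec.seed,
                "min_center_spacing": spec.min_center_spacing,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return paths
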