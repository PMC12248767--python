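"""Nucleus polygon matching by convex-hull overlap.

Each surviving correspondence joins an H&E nucleus (convex hull of its
segmentation label) and a DAPI nucleus (exported boundary polygon, hulled).
After mapping both polygons into a shared frame — scaling the H&E side by
the image-size ratio and centering each polygon at its own bounding-box
midpoint — the intersection area is normalized by the two polygon areas to
give an overlap index (average or minimum proportion).  Pairs below the
threshold join nuclei of inconsistent shape or size and are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as _ShapelyPolygon

from .segmentation import bbox_center

logger = logging.getLogger(__name__)


class DegeneratePolygonError(ValueError):
    """Fewer than 3 points, collinear input, or a zero-area polygon."""


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise vertex order."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class NucleusPolygon:
    """A convex, simple polygon with counterclockwise vertices."""

    vertices: np.ndarray
    source: str | None = None  # "HE" | "DAPI" | None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise DegeneratePolygonError("a polygon needs at least 3 vertices")

    @property
    def area(self) -> float:
        return shoelace_area(self.vertices)


@dataclass
class OverlapScore:
    """Intersection area with its average- and minimum-proportion indexes."""

    intersection_area: float
    index_avg: float
    index_min: float


def convex_hull(points: Sequence, source: str | None = None) -> NucleusPolygon:
    """Quickhull convex hull of a 2-D point set, counterclockwise.

    Degenerate inputs (fewer than 3 points, or all collinear) raise
    :class:`DegeneratePolygonError`; the caller skips such correspondences.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 3:
        raise DegeneratePolygonError("need at least 3 points for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegeneratePolygonError(f"degenerate point set: {exc}") from exc
    return NucleusPolygon(pts[hull.vertices], source=source)


def normalize_pair(
    p_he: NucleusPolygon,
    p_dapi: NucleusPolygon,
    scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[NucleusPolygon, NucleusPolygon]:
    """Map both polygons into a shared frame centered at the origin.

    The H&E polygon is scaled by (sx, sy) = (W_DAPI/W_HE, L_DAPI/L_HE) to
    undo the pixel-grid difference, then each polygon is translated so its
    bounding-box midpoint — the keypoint location — sits at (0, 0), making
    the overlap a pure shape/size comparison.
    """
    sx, sy = scale
    if sx <= 0 or sy <= 0:
        raise ValueError("scale components must be positive")
    he_scaled = p_he.vertices * np.array([sx, sy])
    out = []
    for verts, src in ((he_scaled, p_he.source), (p_dapi.vertices, p_dapi.source)):
        cx, cy = bbox_center(verts)
        out.append(NucleusPolygon(verts - np.array([cx, cy]), source=src))
    return out[0], out[1]


def intersection_area(pa: NucleusPolygon, pb: NucleusPolygon) -> float:
    """Area of the convex intersection of two convex polygons (0 if disjoint)."""
    inter = _ShapelyPolygon(pa.vertices).intersection(_ShapelyPolygon(pb.vertices))
    return float(inter.area)


def overlap_indexes(pa: NucleusPolygon, pb: NucleusPolygon) -> OverlapScore:
    """Average- and minimum-proportion overlap indexes of two polygons.

    With S, T the two polygon areas and A the intersection area:
    index_avg = (A/S + A/T) / 2 and index_min = min(A/S, A/T).
    """
    s, t = pa.area, pb.area
    if s <= 0 or t <= 0:
        raise DegeneratePolygonError("overlap indexes need positive polygon areas")
    a = intersection_area(pa, pb)
    return OverlapScore(
        intersection_area=a,
        index_avg=0.5 * (a / s + a / t),
        index_min=min(a / s, a / t),
    )


def overlap_decision(score: OverlapScore, mode: str, threshold: float) -> bool:
    """Keep a pair iff its overlap index (per mode) reaches the threshold.

    Removal is strict: an index *lower than* the threshold removes the pair.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if mode == "average":
        return score.index_avg >= threshold
    if mode == "minimum":
        return score.index_min >= threshold
    raise ValueError(f"unknown overlap mode: {mode!r}")


def polygon_filter(
    pairs: Iterable[tuple],
    mode: str = "average",
    threshold: float = 0.9,
    scale: tuple[float, float] = (1.0, 1.0),
) -> list:
    """Keep correspondences whose nucleus polygons overlap sufficiently.

    ``pairs`` yields ``(key, he_points, dapi_points)`` with raw boundary
    points per side; hulls are built here and degenerate pairs are dropped
    with a warning.  Returns the kept keys in input order.
    """
    kept = []
    degenerate = 0
    for key, he_points, dapi_points in pairs:
        try:
            p_he = convex_hull(he_points, source="HE")
            p_dapi = convex_hull(dapi_points, source="DAPI")
        except DegeneratePolygonError:
            degenerate += 1
            continue
        p_he, p_dapi = normalize_pair(p_he, p_dapi, scale)
        score = overlap_indexes(p_he, p_dapi)
        if overlap_decision(score, mode, threshold):
            kept.append(key)
    if degenerate:
        logger.warning("dropped %d correspondences with degenerate polygons", degenerate)
    return kept
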