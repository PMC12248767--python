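"""Nucleus records for both modalities.

H&E nuclei come from a pluggable segmentation backend (Cellpose or StarDist
as optional external models, or a supplied ground-truth label image); DAPI
nuclei come from the boundary polygons exported with the Xenium run.  Every
nucleus center is the midpoint of the bounding box of its boundary vertices
(the mean of the min and max coordinate per axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

#: segment_ratio below which the fallback backend is invoked (strict <).
FALLBACK_RATIO = 0.5


class BackendUnavailableError(RuntimeError):
    """An optional segmentation backend is not installed."""


def bbox_center(boundary: np.ndarray) -> tuple[float, float]:
    """Midpoint of the axis-aligned bounding box of (x, y) vertices."""
    b = np.asarray(boundary, dtype=np.float64)
    return (
        float((b[:, 0].min() + b[:, 0].max()) / 2.0),
        float((b[:, 1].min() + b[:, 1].max()) / 2.0),
    )


@dataclass
class NucleusRecord:
    """One nucleus: an id, its boundary vertices and the derived center.

    ``id`` is a label integer for H&E nuclei and a barcode string (e.g.
    ``"gggbgpij-1"``) for DAPI nuclei.  ``boundary`` is an (n, 2) array of
    (x, y) vertices in the source image's pixel coordinates.
    """

    id: int | str
    source: str  # "HE" | "DAPI"
    boundary: np.ndarray
    center: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=np.float64).reshape(-1, 2)
        if len(self.boundary) < 1:
            raise ValueError("boundary requires at least one vertex")
        if self.source not in ("HE", "DAPI"):
            raise ValueError("source must be 'HE' or 'DAPI'")
        if self.center is None:
            self.center = bbox_center(self.boundary)


@dataclass
class SegmentationResult:
    """A label image (0 = background, k > 0 = nucleus k) plus provenance."""

    label_image: np.ndarray
    backend_used: str
    segment_ratio: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.label_image.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        labels = np.unique(self.label_image)
        return int((labels > 0).sum())


def compute_segment_ratio(n_labels: int, expected_cells: int | None) -> float | None:
    """Fraction of expected cells recovered as distinct labels (capped at 1)."""
    if expected_cells is None:
        return None
    if expected_cells <= 0:
        raise ValueError("expected_cells must be positive")
    return min(1.0, n_labels / expected_cells)


def _run_cellpose(he_image: np.ndarray, params: dict) -> np.ndarray:
    try:
        from cellpose import models  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            "the 'cellpose' backend requires the cellpose package "
            "(pip install cellpose); alternatively use backend='stardist' "
            "or supply a label image with backend='ground_truth'"
        ) from exc
    channel = params.get("channel", 1)
    plane = np.asarray(he_image)
    if plane.ndim == 3:
        plane = plane[..., channel]
    model = models.Cellpose(model_type=params.get("model_type", "nuclei"))
    masks, *_ = model.eval(
        plane,
        min_size=params.get("min_size", 15),
        flow_threshold=params.get("flow_threshold", 0.8),
        channels=[0, 0],
    )
    return masks


def _run_stardist(he_image: np.ndarray, params: dict) -> np.ndarray:
    try:
        from stardist.models import StarDist2D  # type: ignore
        from csbdeep.utils import normalize  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            "the 'stardist' backend requires the stardist package "
            "(pip install stardist); alternatively use backend='cellpose' "
            "or supply a label image with backend='ground_truth'"
        ) from exc
    channel = params.get("channel", 1)
    plane = np.asarray(he_image)
    if plane.ndim == 3:
        plane = plane[..., channel]
    model = StarDist2D.from_pretrained(params.get("model_name", "2D_versatile_fluo"))
    labels, _ = model.predict_instances(
        normalize(plane), prob_thresh=params.get("prob_threshold", 0.3)
    )
    return labels


_BACKENDS: dict[str, Callable[[np.ndarray, dict], np.ndarray]] = {
    "cellpose": _run_cellpose,
    "stardist": _run_stardist,
}

#: Hyperparameter defaults for the external backends: Cellpose keeps masks of
#: at least 15 pixels and cells with error below threshold 0.8; StarDist
#: suppresses polygons below object probability 0.3.
BACKEND_DEFAULTS = {
    "cellpose": {"channel": 1, "min_size": 15, "flow_threshold": 0.8},
    "stardist": {"channel": 1, "prob_threshold": 0.3},
}


def segment_he(
    he_image: np.ndarray,
    backend: str = "ground_truth",
    backend_params: dict | None = None,
    expected_cells: int | None = None,
) -> SegmentationResult:
    """Segment nuclei in an H&E raster via the requested backend.

    The ``ground_truth`` backend passes through a label image supplied in
    ``backend_params["label_image"]`` — used for synthetic scenes and
    whenever an external segmentation already exists.
    """
    params = dict(BACKEND_DEFAULTS.get(backend, {}))
    params.update(backend_params or {})
    if backend == "ground_truth":
        if "label_image" not in params:
            raise ValueError(
                "ground_truth backend requires backend_params['label_image']"
            )
        labels = np.asarray(params["label_image"])
    elif backend in _BACKENDS:
        labels = _BACKENDS[backend](np.asarray(he_image), params)
    else:
        raise ValueError(f"unknown segmentation backend: {backend!r}")
    result = SegmentationResult(labels, backend, params={"backend": backend, **params})
    result.segment_ratio = compute_segment_ratio(result.n_labels, expected_cells)
    return result


def apply_fallback_rule(
    primary: SegmentationResult,
    expected_cells: int,
    run_secondary: Callable[[], SegmentationResult],
) -> SegmentationResult:
    """Swap in the secondary backend when the segment ratio is below 50%.

    The rule is strict: a ratio of exactly 0.5 keeps the primary result.
    """
    if expected_cells <= 0:
        raise ValueError("expected_cells must be positive")
    ratio = primary.segment_ratio
    if ratio is None:
        ratio = compute_segment_ratio(primary.n_labels, expected_cells)
        primary.segment_ratio = ratio
    if ratio < FALLBACK_RATIO:
        logger.info(
            "segment ratio %.2f < %.2f: invoking fallback backend",
            ratio,
            FALLBACK_RATIO,
        )
        secondary = run_secondary()
        if secondary.segment_ratio is None:
            secondary.segment_ratio = compute_segment_ratio(
                secondary.n_labels, expected_cells
            )
        return secondary
    return primary


def labels_to_nuclei(seg: SegmentationResult) -> list[NucleusRecord]:
    """One record per distinct nonzero label.

    The boundary is the convex hull of the label's pixel coordinates; labels
    with fewer than 3 pixels (or degenerate, collinear pixel sets) cannot
    form a polygon and are dropped with a logged count.
    """
    labels = seg.label_image
    records: list[NucleusRecord] = []
    dropped = 0
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    boundaries = np.searchsorted(sorted_vals, np.unique(sorted_vals))
    unique_vals = np.unique(sorted_vals)
    for val, start, stop in zip(
        unique_vals,
        boundaries,
        list(boundaries[1:]) + [len(sorted_vals)],
    ):
        if val == 0:
            continue
        idx = order[start:stop]
        rows, cols = np.unravel_index(idx, labels.shape)
        pts = np.column_stack([cols, rows]).astype(np.float64)  # (x, y)
        if len(pts) < 3:
            dropped += 1
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:
            dropped += 1
            continue
        boundary = pts[hull.vertices]
        records.append(NucleusRecord(int(val), "HE", boundary))
    if dropped:
        logger.info("dropped %d labels too small or degenerate for a polygon", dropped)
    return records


def load_dapi_nuclei(
    boundary_source: str | Path | pd.DataFrame,
    id_col: str = "cell_id",
    x_col: str = "vertex_x",
    y_col: str = "vertex_y",
) -> list[NucleusRecord]:
    """Parse exported DAPI nucleus boundary polygons into records.

    Accepts a Xenium-style CSV or parquet path, or an in-memory DataFrame,
    with one row per boundary vertex.  Nuclei with fewer than 3 vertices are
    skipped with a warning.
    """
    if isinstance(boundary_source, (str, Path)):
        path = Path(boundary_source)
        if not path.exists():
            raise IOError(f"boundary file not found: {path}")
        if path.suffix.lower() == ".parquet":
            table = pd.read_parquet(path)
        else:
            table = pd.read_csv(path)
    else:
        table = boundary_source
    missing = {id_col, x_col, y_col} - set(table.columns)
    if missing:
        raise ValueError(f"boundary table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("boundary table is empty")
    records: list[NucleusRecord] = []
    skipped = 0
    for cell_id, group in table.groupby(id_col, sort=False):
        verts = group[[x_col, y_col]].to_numpy(dtype=np.float64)
        if len(verts) < 3:
            skipped += 1
            continue
        records.append(NucleusRecord(cell_id, "DAPI", verts))
    if skipped:
        logger.warning("skipped %d nuclei with fewer than 3 boundary vertices", skipped)
    if not records:
        raise ValueError("boundary table contained no usable nuclei")
    return records
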