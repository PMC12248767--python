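"""End-to-end epoch loop: sample, match, filter, accumulate, emit.

Per epoch, a batch of H&E nuclei is sampled without replacement from the
not-yet-tried pool; each is mapped into the DAPI image, given a search
region, and put through the five-direction PSNR consensus.  The epoch's
consensus pairs then pass the Delaunay edge-consistency filter and the
polygon-overlap filter; survivors accumulate (deduplicated and one-to-one
on both nucleus ids) until the keypoint minimum is met, the pool is
exhausted, or the epoch cap is reached.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .config import PipelineConfig
from .graphs import DegenerateGraphError, build_trigraph, consistency_filter
from .images import (
    GrayImage,
    apply_orientation,
    auto_orient_he,
    invert_orientation,
    load_gray_image,
    to_grayscale_inverted,
)
from .keypoints import KeypointPair, write_keypoint_csv, write_manifest
from .patches import (
    build_search_region,
    consensus_match,
    map_center,
    render_binary_labels,
    crop_directional_patches,
)
from .polygons import polygon_filter
from .segmentation import (
    SegmentationResult,
    apply_fallback_rule,
    labels_to_nuclei,
    load_dapi_nuclei,
    segment_he,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """The pipeline could not produce a usable keypoint set."""


@dataclass
class RunReport:
    """Per-run accounting: epochs, per-epoch survivor counts, skip reasons."""

    epochs_run: int = 0
    keypoints_per_epoch: list[int] = field(default_factory=list)
    total_keypoints: int = 0
    skipped_nuclei_reasons: Counter = field(default_factory=Counter)
    orientation: dict = field(default_factory=dict)
    backend_used: str = ""
    segment_ratio: float | None = None
    he_dims: tuple[int, int] | None = None
    dapi_dims: tuple[int, int] | None = None


def _load_he_rgb(he_image) -> np.ndarray:
    if isinstance(he_image, (str, Path)):
        arr = iio.imread(he_image)
    else:
        arr = np.asarray(he_image)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError("H&E input must be an RGB raster")
    return arr[..., :3]


def run_pipeline(
    cfg: PipelineConfig,
    he_image,
    dapi_image,
    dapi_boundaries,
    label_image: np.ndarray | str | Path | None = None,
    out_csv: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[KeypointPair], RunReport]:
    """Run the full keypoint identification pipeline.

    ``he_image`` is an RGB raster or path; ``dapi_image`` a grayscale image,
    array or path; ``dapi_boundaries`` a boundary table or path.  With the
    ground_truth backend, ``label_image`` supplies the H&E segmentation (in
    the same frame as the H&E raster).  Returns the emitted keypoint pairs
    and a run report; writes the CSV (and JSON manifest) when paths are
    given and at least three pairs survive.
    """
    report = RunReport()
    rng = np.random.default_rng(cfg.rng_seed)

    # --- load & orient -----------------------------------------------------
    he_rgb = _load_he_rgb(he_image)
    if isinstance(dapi_image, (str, Path)):
        dapi = load_gray_image(dapi_image, pyramid_level=cfg.pyramid_level)
    elif isinstance(dapi_image, GrayImage):
        dapi = dapi_image
    else:
        dapi = GrayImage(np.asarray(dapi_image, dtype=np.float64))

    he_gray = to_grayscale_inverted(he_rgb)
    _, applied, _table = auto_orient_he(he_gray, dapi, cfg.thumbnail_side)
    correction = invert_orientation(applied)
    he_rgb = apply_orientation(he_rgb, correction)
    logger.info("H&E orientation detected: %s", applied)
    report.orientation = {"rotation": applied.rotation, "mirrored": applied.mirrored}

    # --- segmentation ------------------------------------------------------
    if isinstance(label_image, (str, Path)):
        label_image = np.asarray(iio.imread(label_image))
    backend_params = dict(cfg.backend_params)
    if cfg.backend == "ground_truth":
        if label_image is None:
            raise PipelineError(
                "ground_truth backend requires a label image input"
            )
        backend_params["label_image"] = apply_orientation(
            np.asarray(label_image), correction
        )

    dapi_nuclei = load_dapi_nuclei(dapi_boundaries)
    expected_cells = len(dapi_nuclei)
    seg = segment_he(
        he_rgb, cfg.backend, backend_params, expected_cells=expected_cells
    )
    if cfg.fallback_backend and cfg.backend != "ground_truth":
        seg = apply_fallback_rule(
            seg,
            expected_cells,
            lambda: segment_he(
                he_rgb, cfg.fallback_backend, None, expected_cells=expected_cells
            ),
        )
    report.backend_used = seg.backend_used
    report.segment_ratio = seg.segment_ratio
    if seg.label_image.shape[:2] != he_rgb.shape[:2]:
        raise PipelineError("label image shape does not match the H&E image")

    he_nuclei = labels_to_nuclei(seg)
    if not he_nuclei:
        raise PipelineError("no nuclei found in the H&E segmentation")
    he_by_id = {rec.id: rec for rec in he_nuclei}
    dapi_by_id = {rec.id: rec for rec in dapi_nuclei}

    he_dims = (he_rgb.shape[1], he_rgb.shape[0])
    dapi_dims = dapi.dims
    report.he_dims, report.dapi_dims = he_dims, dapi_dims
    scale = (dapi_dims[0] / he_dims[0], dapi_dims[1] / he_dims[1])

    # H&E crops use per-axis radii matched to its pixel scale so both
    # modalities' patches cover the same tissue footprint before the common
    # patch-size resize.
    he_crop = (
        max(1, round(cfg.crop_radius_pixel / scale[0])),
        max(1, round(cfg.crop_radius_pixel / scale[1])),
    )
    he_move = (
        round(cfg.center_move_pixel / scale[0]),
        round(cfg.center_move_pixel / scale[1]),
    )
    he_render = render_binary_labels(seg)

    # --- epoch loop --------------------------------------------------------
    pool = sorted(he_by_id)
    accumulated: dict[tuple, KeypointPair] = {}
    used_he: dict = {}
    used_dapi: dict = {}
    patch_cache: dict = {}

    while (
        len(accumulated) < cfg.keypoints_min
        and pool
        and report.epochs_run < cfg.max_epochs
    ):
        report.epochs_run += 1
        n_sample = min(cfg.cell_num_each_epoch, len(pool))
        sampled_idx = rng.choice(len(pool), size=n_sample, replace=False)
        sampled = [pool[i] for i in sorted(sampled_idx)]
        pool = [p for i, p in enumerate(pool) if i not in set(sampled_idx)]

        epoch_matches = []
        for he_id in sampled:
            rec = he_by_id[he_id]
            he_patches = crop_directional_patches(
                he_render, rec.center, he_crop, he_move, cfg.patch_size
            )
            if he_patches is None:
                report.skipped_nuclei_reasons["he_patch_out_of_bounds"] += 1
                continue
            mapped = map_center(rec.center, he_dims, dapi_dims)
            region = build_search_region(
                mapped,
                cfg.crop_radius_ratio,
                dapi_dims,
                dapi_nuclei,
                cfg.extracted_region_min,
            )
            if region is None:
                report.skipped_nuclei_reasons["region_too_few_cells"] += 1
                continue
            match = consensus_match(
                he_patches,
                he_id,
                region,
                dapi,
                dapi_by_id,
                cfg.crop_radius_pixel,
                cfg.center_move_pixel,
                cfg.patch_size,
                patch_cache=patch_cache,
            )
            if match is None:
                report.skipped_nuclei_reasons["no_consensus"] += 1
                continue
            epoch_matches.append(match)

        survivors = _filter_epoch(epoch_matches, he_by_id, dapi_by_id, scale, cfg, report)

        added = 0
        for m in sorted(survivors, key=lambda m: str(m.he_id)):
            key = (m.he_id, m.dapi_id)
            if key in accumulated:
                continue
            if m.he_id in used_he or m.dapi_id in used_dapi:
                report.skipped_nuclei_reasons["conflicting_partner"] += 1
                continue
            he_rec = he_by_id[m.he_id]
            dapi_rec = dapi_by_id[m.dapi_id]
            accumulated[key] = KeypointPair(
                fixed=dapi_rec.center,
                moving=he_rec.center,
                he_id=m.he_id,
                dapi_id=m.dapi_id,
            )
            used_he[m.he_id] = m.dapi_id
            used_dapi[m.dapi_id] = m.he_id
            added += 1
        report.keypoints_per_epoch.append(added)
        logger.info(
            "epoch %d: %d consensus, %d survivors, %d added (total %d)",
            report.epochs_run,
            len(epoch_matches),
            len(survivors),
            added,
            len(accumulated),
        )

    pairs = list(accumulated.values())
    if cfg.final_global_filter and len(pairs) >= 3:
        pairs = _global_delaunay_pass(pairs)
    report.total_keypoints = len(pairs)

    if len(pairs) < 3:
        raise PipelineError(
            f"only {len(pairs)} keypoints found (3 required); "
            f"epochs={report.epochs_run}, "
            f"skip reasons={dict(report.skipped_nuclei_reasons)}"
            + ("; no nuclei matched" if not pairs else "")
        )
    if len(pairs) < cfg.keypoints_min:
        logger.warning(
            "sampling pool exhausted at %d keypoints (minimum requested %d)",
            len(pairs),
            cfg.keypoints_min,
        )

    if out_csv is not None:
        write_keypoint_csv(pairs, out_csv)
        if manifest_path is not None:
            write_manifest(
                manifest_path,
                {
                    "he_dims": he_dims,
                    "dapi_dims": dapi_dims,
                    "orientation_applied_to_he": report.orientation,
                    "backend_used": report.backend_used,
                    "segment_ratio": report.segment_ratio,
                    "epochs_run": report.epochs_run,
                    "total_keypoints": report.total_keypoints,
                    "config": vars(cfg),
                },
            )
    return pairs, report


def _filter_epoch(matches, he_by_id, dapi_by_id, scale, cfg, report):
    """Delaunay edge-consistency then polygon overlap on one epoch's matches."""
    if len(matches) < 3:
        if matches:
            logger.warning(
                "epoch produced %d matches; skipping Delaunay filter", len(matches)
            )
        graph_kept = list(range(len(matches)))
    else:
        pts_he = {i: he_by_id[m.he_id].center for i, m in enumerate(matches)}
        pts_dapi = {i: dapi_by_id[m.dapi_id].center for i, m in enumerate(matches)}
        try:
            ga = build_trigraph(pts_he)
            gb = build_trigraph(pts_dapi)
            graph_kept = consistency_filter(ga, gb)
        except (DegenerateGraphError, ValueError):
            logger.warning("degenerate correspondence geometry; Delaunay filter skipped")
            graph_kept = list(range(len(matches)))
        removed = len(matches) - len(graph_kept)
        if removed:
            report.skipped_nuclei_reasons["delaunay_inconsistent"] += removed

    candidates = [
        (
            i,
            he_by_id[matches[i].he_id].boundary,
            dapi_by_id[matches[i].dapi_id].boundary,
        )
        for i in graph_kept
    ]
    poly_kept = polygon_filter(
        candidates, cfg.overlap_mode, cfg.overlap_threshold, scale
    )
    removed = len(candidates) - len(poly_kept)
    if removed:
        report.skipped_nuclei_reasons["overlap_below_threshold"] += removed
    return [matches[i] for i in poly_kept]


def _global_delaunay_pass(pairs: list[KeypointPair]) -> list[KeypointPair]:
    """Optional final edge-consistency pass over the accumulated set."""
    pts_he = {i: p.moving for i, p in enumerate(pairs)}
    pts_dapi = {i: p.fixed for i, p in enumerate(pairs)}
    try:
        kept = consistency_filter(build_trigraph(pts_he), build_trigraph(pts_dapi))
    except (DegenerateGraphError, ValueError):
        return pairs
    return [pairs[i] for i in kept]
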