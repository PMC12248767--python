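"""Pipeline configuration with tissue-preservation presets.

The fresh-frozen (FF) preset is the default hyperparameter set: 100 cells
sampled per epoch, at least 15 output keypoints, a search-region half-side
of 0.125 x min(W, L) of the DAPI image holding at least 50 nuclei, 400 px
crop radius, 300 px directional move, 224 x 224 patch resize, and an
average-overlap threshold of 0.9.  The FFPE preset halves the crop/move
sizes and lowers the keypoint minimum to 10.  The synthetic preset scales
the pixel-valued parameters down to desk-scale scene sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable hyperparameters of the keypoint identification pipeline."""

    cell_num_each_epoch: int = 100
    keypoints_min: int = 15
    crop_radius_ratio: float = 0.125  # of min(W, L) of the DAPI image
    extracted_region_min: int = 50
    crop_radius_pixel: int = 400
    center_move_pixel: int = 300
    patch_size: int = 224
    overlap_mode: str = "average"  # "average" | "minimum"
    overlap_threshold: float = 0.9
    max_epochs: int = 100
    rng_seed: int = 0
    thumbnail_side: int = 512
    pyramid_level: int = 0
    backend: str = "ground_truth"
    fallback_backend: str | None = "stardist"
    final_global_filter: bool = False
    backend_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "cell_num_each_epoch",
            "keypoints_min",
            "extracted_region_min",
            "crop_radius_pixel",
            "patch_size",
            "max_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.crop_radius_ratio <= 1):
            raise ValueError("crop_radius_ratio must lie in (0, 1]")
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.overlap_mode not in ("average", "minimum"):
            raise ValueError("overlap_mode must be 'average' or 'minimum'")
        if self.center_move_pixel < 0:
            raise ValueError("center_move_pixel must be >= 0")


def ff_preset(**overrides) -> PipelineConfig:
    """Fresh-frozen tissue defaults."""
    return PipelineConfig(**overrides)


def ffpe_preset(**overrides) -> PipelineConfig:
    """FFPE tissue defaults: smaller crops/moves, 10-keypoint minimum."""
    base = dict(
        keypoints_min=10,
        crop_radius_pixel=200,
        center_move_pixel=150,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def synthetic_preset(dapi_dims: tuple[int, int], **overrides) -> PipelineConfig:
    """FF hyperparameters scaled to a desk-scale synthetic scene.

    The pixel-valued crop radius and move distance shrink proportionally to
    the scene's minimum dimension (keeping the 4:3 crop-to-move ratio), and
    the search-region ratio uses the wide 0.5 alternative so that regions
    still collect at least 50 nuclei at synthetic densities.
    """
    min_dim = min(dapi_dims)
    base = dict(
        crop_radius_ratio=0.5,
        crop_radius_pixel=max(16, round(0.10 * min_dim)),
        center_move_pixel=max(12, round(0.075 * min_dim)),
        thumbnail_side=128,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return PipelineConfig(**data)
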