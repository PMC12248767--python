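"""Keypoint alignment file I/O.

Xenium Explorer imports a keypoint CSV with one matched landmark pair per
row: the fixed columns hold DAPI morphology-image pixel coordinates and the
alignment columns hold H&E pixel coordinates.  Explorer refuses files with
fewer than three keypoints, so the writer does too.  A JSON sidecar
manifest records image dimensions, the orientation applied to the H&E, and
the configuration so the CSV stays interpretable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

MIN_KEYPOINTS = 3
DEFAULT_HEADER = ("fixedX", "fixedY", "alignmentX", "alignmentY")


@dataclass
class KeypointPair:
    """One confirmed nucleus correspondence.

    ``fixed`` is the DAPI nucleus center, ``moving`` the H&E nucleus center
    (in the oriented H&E frame).  Provenance ids are kept in memory but not
    stored in the CSV format.
    """

    fixed: tuple[float, float]
    moving: tuple[float, float]
    he_id: int | str | None = None
    dapi_id: int | str | None = None


def write_keypoint_csv(
    pairs: list[KeypointPair],
    path: str | Path,
    header: tuple[str, str, str, str] = DEFAULT_HEADER,
) -> Path:
    """Write pairs as a Xenium Explorer keypoint alignment CSV.

    Coordinates are written with full float precision (repr), UTF-8, LF
    line endings.  Refuses to write fewer than :data:`MIN_KEYPOINTS` pairs.
    """
    if len(pairs) < MIN_KEYPOINTS:
        raise ValueError(
            f"Xenium Explorer requires at least three keypoints in the imported "
            f"file; got {len(pairs)}"
        )
    path = Path(path)
    lines = [",".join(header)]
    for p in pairs:
        lines.append(
            ",".join(repr(float(v)) for v in (*p.fixed, *p.moving))
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_keypoint_csv(
    path: str | Path, header: tuple[str, str, str, str] = DEFAULT_HEADER
) -> list[KeypointPair]:
    """Parse a keypoint alignment CSV back into pairs.

    Provenance ids are absent (the format does not store them).  Malformed
    headers or non-numeric cells raise ``ValueError`` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"keypoint file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or tuple(h.strip() for h in lines[0].split(",")) != header:
        raise ValueError(f"malformed keypoint header on line 1 of {path}")
    pairs: list[KeypointPair] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 4:
            raise ValueError(f"expected 4 cells on line {lineno} of {path}")
        try:
            fx, fy, ax, ay = (float(c) for c in cells)
        except ValueError as exc:
            raise ValueError(
                f"non-numeric cell on line {lineno} of {path}"
            ) from exc
        pairs.append(KeypointPair(fixed=(fx, fy), moving=(ax, ay)))
    if not pairs:
        warnings.warn(f"keypoint file {path} contains a header but no rows")
    return pairs


def write_manifest(path: str | Path, manifest: dict) -> Path:
    """Write the JSON sidecar manifest next to a keypoint CSV."""
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return path
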