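"""Shared fixtures: small synthetic scenes and a similarity-fit helper."""

from __future__ import annotations

import numpy as np
import pytest

from nucalign import OrientationCode, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact identity-orientation scene for per-module tests."""
    spec = SceneSpec(
        n_nuclei=150,
        dapi_dims=(300, 450),
        he_dims=(300, 450),
        seed=5,
        nucleus_radius_range=(3.0, 6.0),
        min_center_spacing=20.0,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def scene_180():
    """A mid-size scene with planted 180-degree orientation and 1.5x scale."""
    spec = SceneSpec(
        n_nuclei=300,
        dapi_dims=(400, 600),
        he_dims=(600, 900),
        orientation=OrientationCode(180, False),
        seed=11,
        min_center_spacing=22.0,
    )
    return generate_scene(spec)


def fit_similarity(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares similarity transform (scale, rotation, translation).

    Umeyama closed form; returns a callable mapping (n, 2) moving points to
    the fixed frame.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    mc, fc = moving - mu_m, fixed - mu_f
    cov = fc.T @ mc / len(moving)
    u, d, vt = np.linalg.svd(cov)
    s = np.eye(2)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s[1, 1] = -1
    rot = u @ s @ vt
    var_m = (mc**2).sum() / len(moving)
    scale = np.trace(np.diag(d) @ s) / var_m
    t = mu_f - scale * rot @ mu_m

    def transform(pts: np.ndarray) -> np.ndarray:
        return (scale * (np.asarray(pts) @ rot.T)) + t

    return transform
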