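"""Shared fixtures: deterministic synthetic volumes and point placements."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from embryosync.simulate import SimulationConfig, render_frame


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=3)


def place_nuclei(
    n: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    min_sep: float = 12.5,
) -> pd.DataFrame:
    """Sample n well-separated positions inside the embryo sphere.

    ``min_sep`` is the minimum pairwise distance in µm.  Returns a one-frame
    coordinate table in isotropic units, grid frame.
    """
    dx = cfg.voxel_spacing[0]
    nz, ny, nx = cfg.grid_shape
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2 * cfg.anisotropy])
    R = (cfg.embryo_radius - cfg.nucleus_radius) / dx
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(-1, 1, 3) * R
        if np.linalg.norm(p) > R:
            continue
        if pts and min(np.linalg.norm(p - q) for q in pts) < min_sep / dx:
            continue
        pts.append(p)
    arr = np.array(pts) + center
    return pd.DataFrame(
        {
            "embryo_id": "fix",
            "frame": 0,
            "time_h": 0.0,
            "x": arr[:, 0],
            "y": arr[:, 1],
            "z": arr[:, 2],
            "volume_voxels": 0.0,
        }
    )


def rendered_fixture(n: int, seed: int, cfg: SimulationConfig):
    """(true coordinate table, rendered noisy volume) for n separated nuclei."""
    rng = np.random.default_rng(seed)
    obs = place_nuclei(n, rng, cfg)
    grid = render_frame(obs, cfg, rng=np.random.default_rng(seed + 1))
    return obs, grid
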