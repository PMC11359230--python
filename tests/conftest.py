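"""Shared fixtures: tiny in-memory scenes and generated scenario pairs."""

from __future__ import annotations

import numpy as np
import pytest

from burnmap import BAND_NAMES, GridGeometry, ScenarioConfig, Scene, generate_scene_pair


def make_scene(values: dict[str, float], n_rows: int = 4, n_cols: int = 5,
               pixel_size: float = 3.0) -> Scene:
    """Uniform scene with the given per-band reflectance (missing bands 0.1)."""
    grid = GridGeometry(n_rows=n_rows, n_cols=n_cols, pixel_size_x=pixel_size,
                        pixel_size_y=pixel_size, origin_x=500_000.0,
                        origin_y=4_100_000.0, crs_epsg=32634)
    bands = np.empty((len(BAND_NAMES), n_rows, n_cols))
    for i, name in enumerate(BAND_NAMES):
        bands[i] = values.get(name, 0.1)
    return Scene(grid=grid, bands=bands,
                 band_map={name: i for i, name in enumerate(BAND_NAMES)})


@pytest.fixture(scope="session")
def small_scenario():
    """120x120 scenario pair with default signatures and noise, plus truth."""
    cfg = ScenarioConfig(n_rows=120, n_cols=120, seed=7)
    pre, post, truth = generate_scene_pair(cfg)
    return cfg, pre, post, truth


@pytest.fixture(scope="session")
def noiseless_scenario():
    cfg = ScenarioConfig(n_rows=80, n_cols=80, noise_sigma=0.0, seed=11)
    pre, post, truth = generate_scene_pair(cfg)
    return cfg, pre, post, truth
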