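import numpy as np
import pytest

from romt import (
    GridSpec,
    ROMTConfig,
    SphereSpec,
    phantom_frames,
    solve_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return GridSpec(5, 4, 3)


def gaussian_blob(grid: GridSpec, center, width=2.0):
    """Flat isotropic Gaussian on a grid, in voxel coordinates."""
    X, Y, Z = np.meshgrid(
        np.arange(grid.nx), np.arange(grid.ny), np.arange(grid.nz), indexing="ij"
    )
    c = np.broadcast_to(np.asarray(center, dtype=float), (3,))
    vol = np.exp(-((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * width**2))
    return grid.to_flat(vol)


@pytest.fixture(scope="session")
def phantom25():
    """Four independent-mode rOMT loops on the half-scale sphere phantom.

    Solved once per session; this is the smoke-scale version of the full
    phantom study (same construction and solver parameters, 25^3 grid)
    shared by the pipeline-level checks.
    """
    spec = SphereSpec(scale=0.5)
    frames, grid = phantom_frames(spec)
    cfg = ROMTConfig(mode="independent")
    flat = [grid.to_flat(f) for f in frames]
    results = [solve_pair(flat[i], flat[i + 1], grid, cfg) for i in range(4)]
    return {
        "spec": spec,
        "frames": frames,
        "flat": flat,
        "grid": grid,
        "cfg": cfg,
        "results": results,
    }
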