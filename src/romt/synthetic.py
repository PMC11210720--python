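"""Gaussian-sphere phantom: a fully synthetic advection-diffusion test case.

Five successive volumes contain an isotropic 3D Gaussian whose center
drifts along the main diagonal (advection) while a Gaussian smoothing
filter of linearly growing width mimics diffusion:

    G_i(x, y, z) = (100 / sqrt(2 pi))
                   * exp(-((x - 0.8 i)^2 + (y - 0.8 i)^2 + (z - 0.8 i)^2) / 2)

evaluated on a symmetric physical grid spanning [-6, 6] per axis with
uniform step 12/49 at the base size of 50^3 (scaled sizes keep the same
physical extent), then smoothed with standard deviation (i + 1) * 0.2
(in physical units) for i >= 1.

Because the construction is known in closed form, approximate ground
truth is available *between* the frames too: the density at sub-step j
of loop i is a Gaussian centered at 0.8 (i + j/m) smoothed with width
(i + j/m + 1) * 0.2.  The mean squared error of the solver's
interpolations against these intermediates measures how faithfully the
recovered dynamics track the true advective-diffusive motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec
from .solver import SolveResult


@dataclass(frozen=True)
class SphereSpec:
    """Phantom construction parameters (defaults: the standard 50^3 set)."""

    base_size: int = 50
    scale: float = 1.0
    num_frames: int = 5
    amplitude: float = 100.0 / np.sqrt(2.0 * np.pi)
    center_step: float = 0.8          # physical drift of the center per frame
    filter_sigma_step: float = 0.2    # physical smoothing-width increment
    half_extent: float = 6.0          # grid spans [-half_extent, +half_extent]

    @property
    def size(self) -> int:
        """Voxels per axis after scaling (e.g. 25, 38, 50, 63, 75, 88).

        Half-up rounding, so a 1.25 scaling of 50 gives 63.
        """
        return int(np.floor(self.base_size * self.scale + 0.5))

    @property
    def step(self) -> float:
        """Physical distance between adjacent grid points (12/49 at base size)."""
        return 2.0 * self.half_extent / (self.size - 1)

    @property
    def coords(self) -> np.ndarray:
        return np.linspace(-self.half_extent, self.half_extent, self.size)

    def grid(self) -> GridSpec:
        return GridSpec(self.size, self.size, self.size)


def _gaussian_volume(center: float, spec: SphereSpec) -> np.ndarray:
    x = spec.coords - center
    g1 = np.exp(-(x**2) / 2.0)
    vol = spec.amplitude * (
        g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    )
    return vol


def _smooth(vol: np.ndarray, sigma_physical: float, spec: SphereSpec) -> np.ndarray:
    # filter width is specified in physical units; nearest-replication at
    # the boundary keeps the filter approximately mass-conserving
    return gaussian_filter(vol, sigma=sigma_physical / spec.step, mode="nearest")


def make_sphere_frame(i: int, spec: SphereSpec = SphereSpec()) -> np.ndarray:
    """Frame i of the phantom as an (N, N, N) volume.

    Frame 0 is the bare Gaussian; frames i >= 1 are additionally smoothed
    with standard deviation (i + 1) * filter_sigma_step.
    """
    if not 0 <= i < spec.num_frames:
        raise IndexError(f"frame index {i} outside 0..{spec.num_frames - 1}")
    vol = _gaussian_volume(spec.center_step * i, spec)
    if i >= 1:
        vol = _smooth(vol, (i + 1) * spec.filter_sigma_step, spec)
    return vol


def phantom_frames(spec: SphereSpec = SphereSpec()) -> tuple[list[np.ndarray], GridSpec]:
    """All frames plus the matching GridSpec."""
    return [make_sphere_frame(i, spec) for i in range(spec.num_frames)], spec.grid()


def make_ground_truth(
    i: int, j: int, m: int, spec: SphereSpec = SphereSpec()
) -> np.ndarray:
    """Approximate true intermediate at sub-step j of loop i.

    A Gaussian centered at 0.8 (i + j/m) per axis, smoothed with width
    (i + j/m + 1) * 0.2; valid for i = 0..num_frames-2, j = 1..m-1.
    """
    if not 0 <= i < spec.num_frames - 1:
        raise IndexError(f"loop index {i} outside 0..{spec.num_frames - 2}")
    if not 1 <= j <= m - 1:
        raise IndexError(f"sub-step index {j} outside 1..{m - 1}")
    t = i + j / m
    vol = _gaussian_volume(spec.center_step * t, spec)
    return _smooth(vol, (t + 1) * spec.filter_sigma_step, spec)


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over voxels of the squared difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def accuracy_curve(
    results: list[SolveResult], spec: SphereSpec, m: int
) -> tuple[list[float], float, float]:
    """MSE of every interpolation against its approximate ground truth.

    Pools sub-steps j = 1..m-1 of all loops in order and returns
    (per-step MSE list, mean, sample standard deviation).
    """
    if len(results) != spec.num_frames - 1:
        raise ValueError(
            f"expected {spec.num_frames - 1} loop results, got {len(results)}"
        )
    grid = spec.grid()
    errors: list[float] = []
    for i, res in enumerate(results):
        if res.interpolations.m != m:
            raise ValueError("result interval count does not match m")
        for j in range(1, m):
            truth = grid.to_flat(make_ground_truth(i, j, m, spec))
            errors.append(mse(res.interpolations.rho[j - 1], truth))
    arr = np.asarray(errors)
    return errors, float(arr.mean()), float(arr.std(ddof=1))
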