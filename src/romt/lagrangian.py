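"""Lagrangian post-processing: pathlines, speed/Peclet lines, maps, flux vectors.

Writing the advection-diffusion equation in conservation form with the
augmented velocity

    v_aug = v - sigma * grad(log rho)

turns diffusion into an extra drift, so particle trajectories under
v_aug carry the full transport (advection plus diffusion).  Pathlines
are traced by explicit Euler through the per-interval augmented fields
and decorated at each step with

* speed  s = ||v||           (the raw optimized velocity, by convention)
* Peclet Pe = ||v|| / (sigma * ||grad log rho||)

the latter being the local ratio of advective to diffusive transport:
high Pe means advection-dominated flow, low Pe diffusion-dominated.

All positions are in voxel coordinates (unit spacing, x-fastest grid of
:mod:`romt.grid`); fields are sampled trilinearly with boundary
clamping, matching the PIC discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .advection import split_components
from .grid import GridSpec
from .solver import ROMTConfig, SolveResult

EMPTY = np.nan  # marker for voxels no pathline sample touched


@dataclass
class Pathline:
    """One particle trajectory with per-step speed and Peclet attributes."""

    seed: np.ndarray            # (3,) starting voxel coordinate
    points: np.ndarray          # (steps + 1, 3)
    speeds: np.ndarray | None = None    # (steps,)
    peclets: np.ndarray | None = None   # (steps,)


class PathlineBundle:
    """A set of pathlines traced together, stored as dense arrays.

    Indexing returns a :class:`Pathline` view; the arrays themselves are
    exposed for vectorized rasterization and export.
    """

    def __init__(self, points: np.ndarray):
        self.points = points            # (lines, steps + 1, 3)
        self.speeds: np.ndarray | None = None   # (lines, steps)
        self.peclets: np.ndarray | None = None  # (lines, steps)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_steps(self) -> int:
        return self.points.shape[1] - 1

    def __getitem__(self, i: int) -> Pathline:
        return Pathline(
            seed=self.points[i, 0],
            points=self.points[i],
            speeds=None if self.speeds is None else self.speeds[i],
            peclets=None if self.peclets is None else self.peclets[i],
        )


@dataclass
class FluxVector:
    """Net displacement of one pathline (start -> end)."""

    start: np.ndarray
    displacement: np.ndarray
    length: float


@dataclass
class ScalarMap:
    """Grid-shaped mean-per-voxel rasterization of a line attribute.

    ``values`` holds NaN (the empty marker) in voxels no sample touched,
    so genuine zeros are never conflated with absence of data.
    """

    values: np.ndarray   # (nx, ny, nz)
    counts: np.ndarray   # (nx, ny, nz) samples per voxel


def _resolve_eps(rho: np.ndarray, eps_log: float | None) -> float:
    top = float(np.max(rho)) if rho.size else 0.0
    if eps_log is not None:
        return eps_log
    return 1e-8 * top if top > 0 else 1e-8


def _grad_log_rho(rho_flat: np.ndarray, eps: float, grid: GridSpec) -> np.ndarray:
    """grad(log(rho + eps)) per component, flat (3n,); central differences
    in the interior, one-sided at boundaries, unit spacing."""
    vol = np.log(grid.to_volume(np.asarray(rho_flat, dtype=float)) + eps)
    grads = [np.zeros_like(vol), np.zeros_like(vol), np.zeros_like(vol)]
    for ax in range(3):
        if vol.shape[ax] > 1:
            grads[ax] = np.gradient(vol, axis=ax)
    return np.concatenate([grid.to_flat(gv) for gv in grads])


def augmented_velocity(
    rho_i: np.ndarray,
    v_i: np.ndarray,
    sigma: float,
    eps_log: float | None,
    grid: GridSpec,
) -> np.ndarray:
    """v - sigma * grad(log(rho + eps)) for one interval, flat (3n,)."""
    v_i = np.asarray(v_i, dtype=float)
    if sigma == 0.0:
        return v_i.copy()
    eps = _resolve_eps(np.asarray(rho_i), eps_log)
    return v_i - sigma * _grad_log_rho(rho_i, eps, grid)


def sample_field(field_flat: np.ndarray, points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Trilinearly sample a flat scalar field at (k, 3) voxel coordinates
    (positions clamped to the domain)."""
    vol = grid.to_volume(np.asarray(field_flat, dtype=float))
    return map_coordinates(vol, np.asarray(points, dtype=float).T, order=1, mode="nearest")


def _sample_vector(vec_flat: np.ndarray, points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Sample a flat (3n,) vector field at (k, 3) points -> (k, 3)."""
    comps = split_components(vec_flat, grid)
    return np.stack([sample_field(c, points, grid) for c in comps], axis=1)


def _clamp(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    hi = np.array([grid.nx - 1, grid.ny - 1, grid.nz - 1], dtype=float)
    return np.clip(points, 0.0, hi)


def seeds_from_volume(
    rho0: np.ndarray,
    grid: GridSpec,
    threshold: float = 0.1,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Seed coordinates: every voxel center where rho0 exceeds
    ``threshold * max(rho0)`` (and lies inside ``mask`` if given)."""
    rho0 = np.asarray(rho0, dtype=float)
    flat = grid.to_flat(rho0) if rho0.ndim == 3 else rho0.reshape(-1)
    keep = flat > threshold * flat.max(initial=0.0)
    if mask is not None:
        mask = np.asarray(mask)
        mflat = grid.to_flat(mask) if mask.ndim == 3 else mask.reshape(-1)
        keep = keep & mflat.astype(bool)
    cx, cy, cz = grid.cell_centers()
    return np.stack([cx[keep], cy[keep], cz[keep]], axis=1).astype(float)


def _iter_intervals(results: list[SolveResult]):
    """Yield (rho at interval start, v of interval) across all loops in order."""
    for res in results:
        m = res.v_star.shape[0]
        for i in range(m):
            yield res.interpolations.at_interval_start(i), res.v_star[i]


def trace_pathlines(
    seeds: np.ndarray,
    results: list[SolveResult],
    grid: GridSpec,
    cfg: ROMTConfig,
) -> PathlineBundle:
    """Trace pathlines through the augmented velocity of every interval of
    every loop (explicit Euler, ``cfg.sub_steps`` sub-steps per interval).

    Seeds outside the domain are skipped (with a warning via logging).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    hi = np.array([grid.nx - 1, grid.ny - 1, grid.nz - 1], dtype=float)
    inside = np.all((seeds >= 0) & (seeds <= hi), axis=1)
    if not np.all(inside):
        import logging
        logging.getLogger(__name__).warning(
            "%d seed(s) outside the domain were skipped", int((~inside).sum())
        )
        seeds = seeds[inside]

    intervals = list(_iter_intervals(results))
    pts = np.empty((seeds.shape[0], len(intervals) + 1, 3))
    pts[:, 0] = seeds
    cur = seeds.copy()
    dt = cfg.kt / cfg.sub_steps
    for t, (rho_i, v_i) in enumerate(intervals):
        v_aug = augmented_velocity(rho_i, v_i, cfg.sigma, cfg.eps_log, grid)
        for _ in range(cfg.sub_steps):
            cur = _clamp(cur + dt * _sample_vector(v_aug, cur, grid), grid)
        pts[:, t + 1] = cur
    return PathlineBundle(pts)


def attach_speed(
    bundle: PathlineBundle, results: list[SolveResult], grid: GridSpec
) -> PathlineBundle:
    """Decorate pathlines with s = ||v|| (raw optimized velocity, not the
    augmented one), sampled at the start of each interval."""
    speeds = np.empty((len(bundle), bundle.n_steps))
    for t, (_, v_i) in enumerate(_iter_intervals(results)):
        speeds[:, t] = np.linalg.norm(_sample_vector(v_i, bundle.points[:, t], grid), axis=1)
    bundle.speeds = speeds
    return bundle


def attach_peclet(
    bundle: PathlineBundle,
    results: list[SolveResult],
    grid: GridSpec,
    cfg: ROMTConfig,
) -> PathlineBundle:
    """Decorate pathlines with Pe = ||v|| / (sigma * ||grad log rho||).

    The denominator is floored at the log epsilon (uniform densities give
    Pe = pe_cap, flagged by capping) and values are capped at
    ``cfg.pe_cap``.  Requires sigma > 0.
    """
    if cfg.sigma <= 0.0:
        raise ValueError(
            "the Peclet number is undefined for sigma = 0 (purely advective "
            "transport has an infinite advection/diffusion ratio)"
        )
    pes = np.empty((len(bundle), bundle.n_steps))
    for t, (rho_i, v_i) in enumerate(_iter_intervals(results)):
        pts = bundle.points[:, t]
        eps = _resolve_eps(np.asarray(rho_i), cfg.eps_log)
        speed = np.linalg.norm(_sample_vector(v_i, pts, grid), axis=1)
        grad = np.linalg.norm(
            _sample_vector(_grad_log_rho(rho_i, eps, grid), pts, grid), axis=1
        )
        denom = np.maximum(cfg.sigma * grad, eps)
        pes[:, t] = np.minimum(speed / denom, cfg.pe_cap)
    bundle.peclets = pes
    return bundle


def rasterize_lines(
    bundle: PathlineBundle, attribute: str, grid: GridSpec
) -> ScalarMap:
    """Bin every (point, value) sample to its nearest voxel and average.

    ``attribute`` is ``"speed"`` or ``"peclet"``; the sample at step t
    uses the pathline point at step t (interval start).
    """
    if attribute == "speed":
        values = bundle.speeds
    elif attribute == "peclet":
        values = bundle.peclets
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    if values is None:
        raise ValueError(f"pathlines carry no {attribute!r} attribute; attach it first")

    pts = bundle.points[:, : values.shape[1]].reshape(-1, 3)
    vals = values.reshape(-1)
    idx = np.rint(_clamp(pts, grid)).astype(int)
    flat = idx[:, 0] + grid.nx * (idx[:, 1] + grid.ny * idx[:, 2])
    sums = np.zeros(grid.n)
    counts = np.zeros(grid.n)
    np.add.at(sums, flat, vals)
    np.add.at(counts, flat, 1.0)
    out = np.full(grid.n, EMPTY)
    hit = counts > 0
    out[hit] = sums[hit] / counts[hit]
    return ScalarMap(values=grid.to_volume(out), counts=grid.to_volume(counts))


def flux_vectors(bundle: PathlineBundle) -> list[FluxVector]:
    """One net-displacement vector per pathline (start point to end point)."""
    starts = bundle.points[:, 0]
    disp = bundle.points[:, -1] - starts
    lengths = np.linalg.norm(disp, axis=1)
    return [
        FluxVector(start=starts[i], displacement=disp[i], length=float(lengths[i]))
        for i in range(len(bundle))
    ]
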