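"""Particle-in-cell (PIC) advection matrices and their velocity Jacobians.

A mass parcel sits at every cell center, is displaced by ``kt * v``
evaluated there, and its mass is spread onto the 8 surrounding cell
centers with trilinear weights.  This yields a sparse column-stochastic
matrix ``S(v)`` (each source voxel's mass is fully reallocated), so
advection conserves total mass to round-off for *any* velocity.

Displaced positions falling outside the domain are clamped to the
boundary, which preserves the column sums.  The velocity Jacobian
``B(rho) = d(S(v) rho)/dv`` is the analytic derivative of the trilinear
weights (one-sided at cell-face kinks, zero where clamping is active),
scaled by ``kt`` and the parcel mass.

Velocity layout: one interval's field is a flat vector of length 3n
ordered ``[u(all voxels), v(all voxels), w(all voxels)]``, each block
x-fastest (see :mod:`romt.grid`).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .grid import GridSpec, TimeGrid


class VelocityError(ValueError):
    """Non-finite or mis-shaped velocity input."""


def split_components(v_i: np.ndarray, grid: GridSpec):
    """Split a per-interval flat velocity (length 3n) into (u, v, w)."""
    v_i = np.asarray(v_i, dtype=float)
    n = grid.n
    if v_i.shape != (3 * n,):
        raise VelocityError(f"expected velocity of length {3 * n}, got {v_i.shape}")
    return v_i[:n], v_i[n:2 * n], v_i[2 * n:]


def _axis_weights(pos: np.ndarray, n_axis: int):
    """Per-axis trilinear data for displaced positions along one axis.

    Returns (i0, frac, dfrac) where the parcel spreads between centers
    i0 and i0+1 with weights (1-frac, frac); dfrac is d(frac)/d(pos),
    which is 1 in the interior and 0 where the position was clamped
    (or on a degenerate single-voxel axis).
    """
    if n_axis == 1:
        z = np.zeros_like(pos)
        return z.astype(int), z, z
    clamped = (pos < 0.0) | (pos > n_axis - 1.0)
    p = np.clip(pos, 0.0, float(n_axis - 1))
    i0 = np.minimum(np.floor(p).astype(int), n_axis - 2)
    frac = p - i0
    dfrac = np.where(clamped, 0.0, 1.0)
    return i0, frac, dfrac


def _displaced(v_i, grid: GridSpec, time: TimeGrid):
    u, v, w = split_components(v_i, grid)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
        raise VelocityError("velocity contains NaN or Inf")
    cx, cy, cz = grid.cell_centers()
    return cx + time.kt * u, cy + time.kt * v, cz + time.kt * w


_CORNERS = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]


def build_pic_matrix(v_i: np.ndarray, grid: GridSpec, time: TimeGrid) -> sp.csr_matrix:
    """Assemble the n x n PIC interpolation matrix S(v_i).

    ``S[dest, src]`` is the trilinear weight with which the parcel from
    voxel ``src``, displaced by ``kt * v_i``, lands on center ``dest``.
    Columns sum to 1; at most 8 nonzeros per column.
    """
    n = grid.n
    px, py, pz = _displaced(v_i, grid, time)
    ix0, fx, _ = _axis_weights(px, grid.nx)
    iy0, fy, _ = _axis_weights(py, grid.ny)
    iz0, fz, _ = _axis_weights(pz, grid.nz)

    cols = np.arange(n)
    rows_all, cols_all, vals_all = [], [], []
    wx = (1.0 - fx, fx)
    wy = (1.0 - fy, fy)
    wz = (1.0 - fz, fz)
    for a, b, c in _CORNERS:
        ia = np.minimum(ix0 + a, grid.nx - 1)
        ib = np.minimum(iy0 + b, grid.ny - 1)
        ic = np.minimum(iz0 + c, grid.nz - 1)
        rows_all.append(ia + grid.nx * (ib + grid.ny * ic))
        cols_all.append(cols)
        vals_all.append(wx[a] * wy[b] * wz[c])
    S = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    )
    return S.tocsr()


def advect(rho: np.ndarray, v_i: np.ndarray, grid: GridSpec, time: TimeGrid) -> np.ndarray:
    """Advect a density one interval: return S(v_i) @ rho."""
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (grid.n,):
        raise ValueError(f"expected density of length {grid.n}, got {rho.shape}")
    return build_pic_matrix(v_i, grid, time) @ rho


def build_pic_jacobian(
    rho_j: np.ndarray, v_j: np.ndarray, grid: GridSpec, time: TimeGrid
) -> sp.csr_matrix:
    """Assemble B(rho_j) = d(S(v_j) rho_j)/dv_j, sparse n x 3n.

    Linear in rho_j.  Column block p of the u-part carries the derivative
    of parcel p's landing weights with respect to its x-displacement,
    scaled by kt and the parcel mass rho_j[p]; likewise for v (y) and
    w (z).  One-sided at trilinear kinks, zero where clamping is active.
    """
    n = grid.n
    rho_j = np.asarray(rho_j, dtype=float)
    if rho_j.shape != (n,):
        raise ValueError(f"expected density of length {n}, got {rho_j.shape}")
    px, py, pz = _displaced(v_j, grid, time)
    ix0, fx, dfx = _axis_weights(px, grid.nx)
    iy0, fy, dfy = _axis_weights(py, grid.ny)
    iz0, fz, dfz = _axis_weights(pz, grid.nz)

    kt = time.kt
    cols = np.arange(n)
    wx = (1.0 - fx, fx)
    wy = (1.0 - fy, fy)
    wz = (1.0 - fz, fz)
    # d(weight)/d(position) per corner along each axis, 0 when clamped
    gx = (-dfx, dfx)
    gy = (-dfy, dfy)
    gz = (-dfz, dfz)

    rows_all, cols_all, vals_all = [], [], []
    scale = kt * rho_j
    for a, b, c in _CORNERS:
        ia = np.minimum(ix0 + a, grid.nx - 1)
        ib = np.minimum(iy0 + b, grid.ny - 1)
        ic = np.minimum(iz0 + c, grid.nz - 1)
        dest = ia + grid.nx * (ib + grid.ny * ic)
        for comp, dw in enumerate(
            (gx[a] * wy[b] * wz[c], wx[a] * gy[b] * wz[c], wx[a] * wy[b] * gz[c])
        ):
            rows_all.append(dest)
            cols_all.append(comp * n + cols)
            vals_all.append(scale * dw)
    B = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, 3 * n),
    )
    return B.tocsr()
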