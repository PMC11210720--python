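"""Forward advection-diffusion model and matrix-free sensitivity products.

One time interval advances the density by an operator split: a PIC
advection step followed by an implicit Euler diffusion step,

    rho_{i+1} = L^{-1} S(v_i) rho_i ,

so the state after k intervals is a product of lower-triangular factors
and the Jacobian J = d rho / d v is block lower-triangular: rho_k depends
on v_0..v_{k-1} only.  Its blocks for j < k are

    J^k_{v_j} = L^{-1} S(v_{k-1}) ... L^{-1} S(v_{j+1}) L^{-1} B(rho_j)

with B(rho_j) the PIC velocity Jacobian at interval start.  Both J_m x
(final-row product) and J^T y (full adjoint) are computed matrix-free by
forward/backward sweeps over cached S and B matrices; L is symmetric so
its factorization serves both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .advection import build_pic_jacobian, build_pic_matrix
from .grid import DiffusionOperator, GridSpec, TimeGrid


class StaleCacheError(RuntimeError):
    """Sensitivity cache does not correspond to the supplied velocity."""


@dataclass
class DensitySequence:
    """rho_0 plus the m interpolations rho_1..rho_m (rows of ``rho``)."""

    rho0: np.ndarray          # (n,)
    rho: np.ndarray           # (m, n), row k-1 is rho_k

    @property
    def m(self) -> int:
        return self.rho.shape[0]

    @property
    def final(self) -> np.ndarray:
        return self.rho[-1]

    def at_interval_start(self, j: int) -> np.ndarray:
        """rho_j, the density at the start of interval j (j = 0..m-1)."""
        return self.rho0 if j == 0 else self.rho[j - 1]

    @property
    def stacked(self) -> np.ndarray:
        """(rho_1; ...; rho_m) as one vector of length m*n."""
        return self.rho.reshape(-1)


def advdiff_step(
    rho_i: np.ndarray, v_i: np.ndarray, op: DiffusionOperator
) -> np.ndarray:
    """One interval of the forward model: L^{-1} S(v_i) rho_i."""
    S = build_pic_matrix(v_i, op.grid, op.time)
    return op.solve(S @ np.asarray(rho_i, dtype=float))


def forward_integrate(
    rho_0: np.ndarray, v: np.ndarray, op: DiffusionOperator
) -> DensitySequence:
    """Run the m-interval forward recursion from rho_0 under velocity v.

    ``v`` has shape (m, 3n) (one flat per-interval field per row).
    """
    v = np.asarray(v, dtype=float)
    m = op.time.m
    n = op.grid.n
    if v.shape != (m, 3 * n):
        raise ValueError(f"expected velocity of shape {(m, 3 * n)}, got {v.shape}")
    rho = np.empty((m, n))
    cur = np.asarray(rho_0, dtype=float)
    for i in range(m):
        cur = advdiff_step(cur, v[i], op)
        rho[i] = cur
    return DensitySequence(rho0=np.asarray(rho_0, dtype=float), rho=rho)


@dataclass
class SensitivityCache:
    """Precomputed S(v_j) and B(rho_j) for all intervals of one (v, rho) pair.

    Assembled once per Gauss-Newton iteration and shared by every
    J/J^T product of that iteration; invalidated when v changes.
    """

    op: DiffusionOperator
    seq: DensitySequence
    v: np.ndarray                     # (m, 3n) snapshot the cache was built from
    S: list[sp.csr_matrix]
    B: list[sp.csr_matrix]

    @property
    def m(self) -> int:
        return len(self.S)

    def check_current(self, v: np.ndarray) -> None:
        v = np.asarray(v)
        if v.shape != self.v.shape or not np.array_equal(v, self.v):
            raise StaleCacheError(
                "sensitivity cache was built for a different velocity; rebuild it"
            )


def build_sensitivity_cache(
    seq: DensitySequence, v: np.ndarray, op: DiffusionOperator
) -> SensitivityCache:
    """Assemble all S(v_j) and B(rho_j), j = 0..m-1, for the given state."""
    v = np.asarray(v, dtype=float)
    grid, time = op.grid, op.time
    S = [build_pic_matrix(v[j], grid, time) for j in range(time.m)]
    B = [
        build_pic_jacobian(seq.at_interval_start(j), v[j], grid, time)
        for j in range(time.m)
    ]
    return SensitivityCache(op=op, seq=seq, v=v.copy(), S=S, B=B)


def jac_final_vec(x: np.ndarray, cache: SensitivityCache) -> np.ndarray:
    """J_m @ x for a velocity-space vector x of length 3mn.

    Forward sweep: w <- L^{-1} (S_j w + B_j x_j) accumulates every block
    of the final Jacobian row in one pass.
    """
    m, n = cache.m, cache.op.grid.n
    x = np.asarray(x, dtype=float).reshape(m, 3 * n)
    w = np.zeros(n)
    for j in range(m):
        w = cache.op.solve(cache.S[j] @ w + cache.B[j] @ x[j])
    return w


def jacT_final_vec(y: np.ndarray, cache: SensitivityCache) -> np.ndarray:
    """J_m^T @ y for a density-space vector y of length n (adjoint sweep)."""
    m, n = cache.m, cache.op.grid.n
    out = np.empty((m, 3 * n))
    a = cache.op.solve(np.asarray(y, dtype=float))
    for j in range(m - 1, -1, -1):
        out[j] = cache.B[j].T @ a
        if j > 0:
            a = cache.op.solve(cache.S[j].T @ a)
    return out.reshape(-1)


def jacT_full_vec(y: np.ndarray, cache: SensitivityCache) -> np.ndarray:
    """J^T @ y for a stacked vector y = (y_1; ...; y_m) of length mn.

    Single backward (adjoint) sweep over the block rows of J: the running
    adjoint state picks up y_k before each L-solve, and B_j^T reads it
    off for block j = k-1.
    """
    m, n = cache.m, cache.op.grid.n
    y = np.asarray(y, dtype=float).reshape(m, n)
    out = np.empty((m, 3 * n))
    a = np.zeros(n)
    for k in range(m, 0, -1):
        a = cache.op.solve(y[k - 1] + a)
        out[k - 1] = cache.B[k - 1].T @ a
        if k > 1:
            a = cache.S[k - 1].T @ a
    return out.reshape(-1)
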