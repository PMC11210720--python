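"""Discrete free-end-point rOMT objective and its Gauss-Newton solver.

The objective over the velocity field v = (v_0; ...; v_{m-1}) is

    F(v) = ks*kt * rho^T M (v .* v)  +  beta * || rho_m - rho1_obs ||^2

where rho = (rho_1; ...; rho_m) follows the advection-diffusion
recursion (see :mod:`romt.transport`), M = I_m (x) [I_n | I_n | I_n]
sums squared velocity components per voxel, and the terminal constraint
is relaxed to a weighted fitting term so that image noise in the target
frame is not matched exactly.

Gradient and Gauss-Newton Hessian action (both matrix-free):

    g  = ks*kt * ( 2 v .* M^T rho  +  J^T M (v .* v) )
         + 2 beta * J_m^T (rho_m - rho1_obs)
    Hx = 2 ks*kt * (M^T rho) .* x  +  2 beta * J_m^T (J_m x)

The inner system H x = -g is solved by preconditioned conjugate
gradients; a backtracking line search on the total cost accepts the
step.  Optimizing v directly (rather than the momentum rho*v) keeps the
objective finite where the density vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from joblib import Parallel, delayed
from scipy.sparse.linalg import LinearOperator, cg

from .grid import DiffusionOperator, GridSpec, TimeGrid, build_diffusion_operator
from .transport import (
    DensitySequence,
    SensitivityCache,
    build_sensitivity_cache,
    forward_integrate,
    jacT_final_vec,
    jacT_full_vec,
    jac_final_vec,
)

logger = logging.getLogger(__name__)


@dataclass
class ROMTConfig:
    """Solver parameters.  Defaults are the standard geometric-data set:
    m = 10 intervals of kt = 0.4, ks = 1, sigma = 0.002, beta = 5000.
    """

    sigma: float = 0.002        # diffusion coefficient
    beta: float = 5000.0        # terminal-fitting weight
    m: int = 10                 # number of time intervals
    kt: float = 0.4             # interval length
    ks: float = 1.0             # spatial quadrature weight
    gn_max_iter: int = 20       # outer Gauss-Newton iterations
    pcg_rel_tol: float = 1e-2   # inner CG relative tolerance (inexact Newton)
    pcg_max_iter: int = 20      # inner CG iteration cap
    ls_max_backtracks: int = 15
    ls_shrink: float = 0.5      # step shrink factor per backtrack
    eps_log: float | None = None  # floor for log/division; None = 1e-8 * max(rho)
    pe_cap: float = 100.0       # Peclet rasterization cap
    mode: str = "chained"       # chained | independent multi-frame sequencing
    n_jobs: int = 1             # workers for independent mode
    precond: str = "diag"       # diag | identity CG preconditioner
    sub_steps: int = 1          # Euler sub-steps per interval in pathline tracing
    seed_threshold: float = 0.1  # pathline seeding: fraction of frame max

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if min(self.gn_max_iter, self.pcg_max_iter, self.ls_max_backtracks) < 1:
            raise ValueError("iteration caps must be >= 1")
        if not 0.0 < self.ls_shrink < 1.0:
            raise ValueError("ls_shrink must lie in (0, 1)")
        if self.mode not in ("chained", "independent"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def time_grid(self) -> TimeGrid:
        return TimeGrid(m=self.m, kt=self.kt)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CostBreakdown:
    total: float
    energy: float
    fit: float


@dataclass
class SolveResult:
    """Optimized velocity, the interpolations it induces, and the cost log."""

    v_star: np.ndarray                 # (m, 3n)
    interpolations: DensitySequence
    cost_history: list[CostBreakdown]  # entry 0 at v = 0, then accepted iterates
    termination: str                   # converged | line-search-failed | max-iter


def _rep3(rho_stack: np.ndarray) -> np.ndarray:
    """M^T rho: replicate each interval's density across 3 components; (m, 3n)."""
    return np.tile(rho_stack, (1, 3))


def _energy_density(v: np.ndarray, n: int) -> np.ndarray:
    """M (v .* v): per-interval voxelwise u^2 + v^2 + w^2; shape (m, n)."""
    vv = v * v
    return vv[:, :n] + vv[:, n:2 * n] + vv[:, 2 * n:]


class ROMTProblem:
    """One frame pair's optimization workspace (grid, time grid, L-factorization)."""

    def __init__(self, grid: GridSpec, cfg: ROMTConfig):
        self.grid = grid
        self.cfg = cfg
        self.time = cfg.time_grid()
        self.op: DiffusionOperator = build_diffusion_operator(grid, self.time, cfg.sigma)

    # -- objective -----------------------------------------------------

    def cost_of_sequence(
        self, seq: DensitySequence, v: np.ndarray, rho1_obs: np.ndarray
    ) -> CostBreakdown:
        cfg, n = self.cfg, self.grid.n
        energy = cfg.ks * cfg.kt * float(np.sum(seq.rho * _energy_density(v, n)))
        resid = seq.final - rho1_obs
        fit = cfg.beta * float(resid @ resid)
        total = energy + fit
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite cost (energy={energy}, fit={fit}); "
                "check inputs for NaN/Inf or reduce the step"
            )
        return CostBreakdown(total=total, energy=energy, fit=fit)

    def cost(
        self, v: np.ndarray, rho0: np.ndarray, rho1_obs: np.ndarray
    ) -> CostBreakdown:
        """F(v) with its kinetic-energy and terminal-fitting terms."""
        seq = forward_integrate(rho0, v, self.op)
        return self.cost_of_sequence(seq, v, rho1_obs)

    def gradient(
        self, v: np.ndarray, rho1_obs: np.ndarray, cache: SensitivityCache
    ) -> np.ndarray:
        """dF/dv as a flat vector of length 3mn."""
        cache.check_current(v)
        cfg, n = self.cfg, self.grid.n
        seq = cache.seq
        g = 2.0 * v * _rep3(seq.rho)                              # (M diag v)^T rho term
        g = g.reshape(-1) + jacT_full_vec(_energy_density(v, n).reshape(-1), cache)
        g *= cfg.ks * cfg.kt
        g += 2.0 * cfg.beta * jacT_final_vec(seq.final - rho1_obs, cache)
        return g

    def hess_vec(self, v: np.ndarray, x: np.ndarray, cache: SensitivityCache) -> np.ndarray:
        """Gauss-Newton Hessian action H @ x (symmetric PSD)."""
        cache.check_current(v)
        cfg = self.cfg
        diag = 2.0 * cfg.ks * cfg.kt * _rep3(cache.seq.rho).reshape(-1)
        return diag * x + 2.0 * cfg.beta * jacT_final_vec(jac_final_vec(x, cache), cache)

    # -- Gauss-Newton --------------------------------------------------

    def _preconditioner(self, cache: SensitivityCache) -> LinearOperator | None:
        if self.cfg.precond == "identity":
            return None
        d = 2.0 * self.cfg.ks * self.cfg.kt * _rep3(cache.seq.rho).reshape(-1)
        top = d.max(initial=0.0)
        if top <= 0.0:
            return None
        d = d + 1e-6 * top  # keep SPD where the density vanishes
        return LinearOperator(shape=(d.size, d.size), matvec=lambda r: r / d)

    def solve_pair(self, rho0: np.ndarray, rho1_obs: np.ndarray) -> SolveResult:
        """Gauss-Newton with inexact CG inner solves and backtracking line search."""
        cfg = self.cfg
        n, m = self.grid.n, self.time.m
        rho0 = np.asarray(rho0, dtype=float)
        rho1_obs = np.asarray(rho1_obs, dtype=float)
        if np.any(rho0 < 0) or np.any(rho1_obs < 0):
            raise ValueError("densities must be non-negative (clip inputs upstream)")

        v = np.zeros((m, 3 * n))
        seq = forward_integrate(rho0, v, self.op)
        current = self.cost_of_sequence(seq, v, rho1_obs)
        history = [current]
        termination = "max-iter"
        dim = 3 * m * n

        for it in range(cfg.gn_max_iter):
            cache = build_sensitivity_cache(seq, v, self.op)
            g = self.gradient(v, rho1_obs, cache)
            gnorm = float(np.linalg.norm(g))
            if gnorm == 0.0:
                termination = "converged"
                break
            H = LinearOperator(
                shape=(dim, dim), matvec=lambda x: self.hess_vec(v, x, cache)
            )
            x, info = cg(
                H, -g, rtol=cfg.pcg_rel_tol, atol=0.0,
                maxiter=cfg.pcg_max_iter, M=self._preconditioner(cache),
            )
            if not np.all(np.isfinite(x)) or float(g @ x) >= 0.0:
                logger.warning(
                    "iter %d: CG produced a non-descent direction (info=%s); "
                    "falling back to steepest descent", it, info,
                )
                x = -g
            step = x.reshape(m, 3 * n)

            # backtracking line search: simple decrease of the total cost
            length = 1.0
            accepted = False
            for _ in range(cfg.ls_max_backtracks):
                v_try = v + length * step
                seq_try = forward_integrate(rho0, v_try, self.op)
                trial = self.cost_of_sequence(seq_try, v_try, rho1_obs)
                if trial.total < current.total:
                    accepted = True
                    break
                length *= cfg.ls_shrink
            if not accepted:
                termination = "line-search-failed"
                break
            v, seq, current = v_try, seq_try, trial
            history.append(current)
            logger.info(
                "iter %d: total=%.6g energy=%.6g fit=%.6g step=%.3g |g|=%.3g",
                it, current.total, current.energy, current.fit, length, gnorm,
            )

        return SolveResult(
            v_star=v, interpolations=seq, cost_history=history, termination=termination
        )


def solve_pair(
    rho0: np.ndarray, rho1_obs: np.ndarray, grid: GridSpec, cfg: ROMTConfig
) -> SolveResult:
    """Optimize one frame pair starting from v = 0."""
    return ROMTProblem(grid, cfg).solve_pair(rho0, rho1_obs)


def solve_sequence(
    frames: list[np.ndarray], grid: GridSpec, cfg: ROMTConfig
) -> list[SolveResult]:
    """Run p-1 rOMT loops over p successive frames.

    ``chained`` mode feeds each loop's final interpolation in as the next
    loop's source (serial by construction, smoother velocity fields);
    ``independent`` mode pairs observed frames directly and may run loops
    in parallel (results identical to serial execution).
    """
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, got {len(frames)}")
    flat = [np.asarray(f, dtype=float).reshape(-1) for f in frames]
    for f in flat:
        if f.shape != (grid.n,):
            raise ValueError("all frames must match the grid voxel count")

    if cfg.mode == "chained":
        results = []
        source = flat[0]
        problem = ROMTProblem(grid, cfg)
        for target in flat[1:]:
            res = problem.solve_pair(source, target)
            results.append(res)
            source = res.interpolations.final
        return results

    pairs = list(zip(flat[:-1], flat[1:]))
    if cfg.n_jobs == 1:
        return [solve_pair(a, b, grid, cfg) for a, b in pairs]
    return Parallel(n_jobs=cfg.n_jobs)(
        delayed(solve_pair)(a, b, grid, cfg) for a, b in pairs
    )
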