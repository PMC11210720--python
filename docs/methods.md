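# Methods

## Model

`romt` estimates the fluid motion that carries one non-negative 3D image
into the next.  Image intensity is treated as the density ρ of a passive
tracer; the flow is the velocity field v that minimizes the kinetic
energy

    F(v) = ks·kt · ρᵀ M (v ⊙ v)  +  β ‖ρ_m − ρ₁ᵒᵇˢ‖²

subject to the advection–diffusion recursion

    ρ_{i+1} = L⁻¹ S(v_i) ρ_i ,    i = 0 … m−1,    ρ₀ = ρ₀ᵒᵇˢ,

the dynamic (Benamou–Brenier) optimal-transport formulation with the
continuity equation replaced by an advection–diffusion equation
∂ρ/∂t + ∇·(ρv) = σΔρ.  The terminal condition is *free*: instead of
forcing ρ(1,·) to equal the observed target frame — which would chase
image noise — a weighted squared mismatch (weight β) is added to the
cost.  The optimization variable is v, not the momentum ρv; this keeps
the objective finite where ρ vanishes, which happens routinely in
DCE-MRI backgrounds.

One time interval is advanced by operator splitting:

* **Advection** — a particle-in-cell step.  A parcel at each cell
  center is displaced by kt·v evaluated there and its mass is spread
  over the 8 surrounding centers with trilinear weights, giving a
  sparse column-stochastic matrix S(v).  Column-stochasticity makes
  advection conserve total mass to round-off for *any* velocity;
  parcels displaced outside the domain are clamped to the boundary,
  which preserves the column sums (dropping them would leak mass).
* **Diffusion** — one backward-Euler step with the 7-point
  discretization Q of σΔ on the cell-centered grid, i.e. a solve with
  L = I − kt·Q.  Backward Euler is unconditionally stable, and with
  homogeneous Neumann (zero-flux) boundaries the step is exactly
  mass-conserving (1ᵀL = 1ᵀ) and positivity-preserving (L is an
  M-matrix).  The boundary condition is a modeling choice: zero flux is
  what makes the conservation-form argument behind the augmented
  velocity (below) exact on a closed domain.

Stencils use unit voxel spacing; the scalar ks enters only as the
quadrature weight of the energy term (ks = 1 in the standard setting).
All volumes are flattened x-fastest (Fortran order of an
(nx, ny, nz) array); one interval's velocity is stored as
[u; v; w], each block of length n.

## Optimization

Gauss–Newton.  ρ depends on v through the forward recursion, and the
chain rule gives the gradient and a positive-semidefinite Hessian
approximation

    g  = ks·kt (2 v ⊙ Mᵀρ + Jᵀ M(v⊙v)) + 2β J_mᵀ (ρ_m − ρ₁ᵒᵇˢ)
    Hx = 2 ks·kt (Mᵀρ) ⊙ x + 2β J_mᵀ J_m x

where J = ∂ρ/∂v is block lower-triangular (ρ_k depends only on
v_0…v_{k−1}) with blocks L⁻¹S(v_{k−1})⋯L⁻¹S(v_{j+1})L⁻¹B(ρ_j), and
B(ρ) = ∂(S(v)ρ)/∂v is the analytic trilinear-weight derivative, linear
in ρ.  J is never assembled: J_m·x is one forward sweep over the cached
S and B factors, Jᵀ·y one backward (adjoint) sweep; L is symmetric so
one solve routine serves both.  All S(v_j) and B(ρ_j) are assembled
once per outer iteration and shared by every product of that iteration.
The trilinear weight derivative is one-sided at cell-face crossings (a
measure-zero set) and zero where boundary clamping is active.

Each outer iteration solves H x = −g inexactly by preconditioned
conjugate gradients (relative tolerance 1e−2, ≤ 20 iterations,
preconditioner = the diagonal energy term of H floored to stay SPD
where ρ ≈ 0), then backtracks a step length from 1 by halving until
the *total* cost decreases (≤ 15 backtracks).  Plain decrease is used
rather than an Armijo condition; failure to decrease terminates the
solve and returns the current iterate, which doubles as the
convergence signal of the method.  If CG returns a non-descent or
non-finite direction the iteration falls back to steepest descent.
Defaults: 20 outer iterations, initial v = 0.  These inner/outer
controls follow common inexact-Newton practice; none of them is
physically meaningful and all are config-exposed.

### The implicit-diffusion solve

L is fixed for a given (grid, σ, kt) and applied thousands of times per
solve, so its inner solve dominates runtime.  When kt·Q is a strong
contraction (2·kt·max|diag Q| < 0.25 — amply satisfied by the standard
σ = 0.002, kt = 0.4, where it is ≈ 0.01), L x = b is solved by the
Neumann fixed point x ← b + kt·Q x iterated to a 1e−14 relative
residual: each iteration is one 7-point matvec, convergence is
geometric with ratio ≈ the contraction factor, every truncation of the
series conserves total mass *exactly* (all terms beyond the first have
zero column sum), and the result matches a dense solve to machine
precision on small grids.  Outside the contractive regime a sparse LU
factorization is computed once and reused.  This choice cut end-to-end
solve time by roughly 6× at 25³ relative to applying the LU factors
everywhere.

### Multi-frame sequencing

For p > 2 frames the solver runs p−1 loops. `independent` mode pairs
observed frames (ρ_iᵒᵇˢ → ρ_{i+1}ᵒᵇˢ); loops share no state and may run
in parallel with bit-identical results. `chained` mode feeds each
loop's final interpolation in as the next loop's source, avoiding
re-injection of observation noise at every loop boundary at the price
of serial execution; velocity fields join more smoothly across loops.

## Lagrangian post-processing

Rewriting the advection–diffusion equation in conservation form defines
the augmented velocity ṽ = v − σ∇log ρ, under which particle
trajectories carry the *total* transport (bulk flow plus diffusive
drift).  Pathlines are traced from seeds at every voxel center whose
initial intensity exceeds 10 % of the frame maximum (and inside the
mask, if any) by explicit Euler: one step of kt·ṽ per interval
(sub-steps configurable), ṽ rebuilt per interval from (ρ_i, v_i),
trilinear field sampling, positions clamped to the domain.  Attributes
are sampled at the start of each interval at the current point:

* speed s = ‖v‖ — the *raw* optimized velocity, not ṽ (the
  conventional definition; the asymmetry with the tracing field is
  deliberate and preserved);
* Péclet number Pe = ‖v‖ / (σ‖∇log ρ‖) — the local ratio of advective
  to diffusive transport.  σ = 0 is rejected (Pe would be identically
  infinite).  The denominator is floored at the log epsilon, so
  uniform-density regions report the cap value rather than dividing by
  zero.

∇log(ρ + ε) uses central differences (one-sided at boundaries) with
ε = 1e−8 · max ρ by default.  Speed-lines and Péclet-lines are
rasterized to maps by binning each (point, value) sample to its nearest
voxel and averaging; untouched voxels carry NaN so genuine zeros are
never conflated with absence of data.  Flux vectors connect each
pathline's start to its end point.

The Pe values are capped at `pe_cap` (default 100) for line attributes
and rasterization.  The cap bounds the floored-denominator artifact
(uniform ρ) and compresses the heavy right tail of Pe.  Caveat: with
σ = 0.002 and voxel-unit gradients, raw phantom Pe values are
O(10²–10³), so at the default cap most phantom samples saturate; raise
`pe_cap` when the absolute Pe scale (rather than its spatial contrast)
is of interest.  On the half-scale phantom the *uncapped* mean Pe grows
from loop to loop — progressive smoothing shrinks ‖∇log ρ‖ faster than
the recovered speed decays — while at full scale the capped per-loop
mean falls as an increasing share of lagging, low-speed particles drops
below the cap.  Pooled Pe statistics on this phantom are therefore
scale- and cap-sensitive and should be read qualitatively.

## Synthetic phantom

Five 50³ frames contain an isotropic Gaussian (amplitude 100/√(2π),
unit width) whose center drifts 0.8 physical units per frame along the
main diagonal; frames i ≥ 1 are additionally smoothed with a Gaussian
filter of standard deviation (i+1)·0.2, emulating diffusion.  The grid
spans [−6, 6] per axis symmetrically (uniform step 12/49 at base size;
scaled sizes keep the extent and rescale the step).  The symmetric
placement keeps all sphere centers (0 … 3.2) well inside the domain;
the domain offset is otherwise arbitrary and config-exposed.  Filter
widths are interpreted in physical units and converted to voxels via
the step, which keeps the construction consistent across scaled grids;
the filter uses nearest-replication at the boundary.

Two caveats this generator documents rather than hides: (i) it is not
exactly mass-conserving — the widest frames push a few percent of their
tails past the domain edge, so frame masses agree only to ≈ 4 %, and
(ii) the origin is not a grid point on the symmetric grid, so the peak
of the unsmoothed frame is amplitude·exp(−3(step/2)²/2) ≈ 39.0, just
below the analytic 39.894.

Because the construction is known in closed form, approximate ground
truth exists *between* frames: the intermediate at sub-step j of loop i
is a Gaussian centered at 0.8(i + j/m) smoothed with width
(i + j/m + 1)·0.2.  The accuracy harness pools the MSE of every
interpolation (j = 1…m−1, all loops) against these intermediates and
reports mean ± sample standard deviation.  What the phantom does *not*
emulate: observation noise, anatomy-shaped masks, spatially varying
diffusivity, and intensity that is a nonlinear function of tracer
concentration — phantom results bound algorithmic, not physiological,
fidelity.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| σ (`sigma`) | diffusion coefficient | 0.002 | grid units²/time; 0 recovers pure OMT |
| β (`beta`) | terminal-fit weight | 5000 | larger = tighter endpoint match, more noise chasing |
| m | time intervals per loop | 10 | |
| kt | interval length | 0.4 | displacement per step is kt·v |
| ks | voxel quadrature weight | 1 | scales the energy term only |
| `gn_max_iter` | outer iterations | 20 | |
| `pcg_rel_tol`, `pcg_max_iter` | inner CG controls | 1e−2, 20 | inexact Newton |
| `ls_max_backtracks`, `ls_shrink` | line search | 15, 0.5 | plain-decrease acceptance |
| `eps_log` | log/division floor | 1e−8·max ρ | Lagrangian layer only |
| `pe_cap` | Pe attribute/rasterization cap | 100 | see caveat above |
| `seed_threshold` | pathline seeding | 0.1 | fraction of frame max |
| `sub_steps` | Euler sub-steps per interval | 1 | |

## Numerical choices and degenerate inputs

* Linear indexing is x-fastest everywhere; a single pair of helpers
  converts between flat vectors and (nx, ny, nz) volumes.
* Single-voxel axes degrade gracefully: the 1D stencil and the
  trilinear weights collapse to identities along that axis.
* Negative input intensities are clipped at load time; the solver
  rejects negative densities outright.
* Identical source/target with σ = 0 yields an exactly zero gradient at
  v = 0 and the solver terminates immediately as converged.
* Determinism: the entire pipeline is free of randomness; independent
  loops return bit-identical results at any worker count.

## Problem sizes

The test suite exercises the full pipeline at the 25³ phantom scale
(4 independent loops, standard parameters, ≈ 0.5 min per loop) and all
operator/derivative checks on grids of ≤ 6³ with m ≤ 3, where dense
oracles are feasible.  `scripts/acceptance.py` defaults to the same 25³
study and reproduces the full 50³ study with `--size 50` (about ten
times longer).

## Known limitations

* Constant scalar σ; no spatially varying or anisotropic diffusion.
* No source term: total mass is conserved by construction, so
  acquisition effects that create/destroy signal must be handled
  upstream.
* Explicit Euler tracing; one PIC step per interval (no sub-stepping of
  the forward model).
* The free end-point still passes some observation noise into the
  recovered fields; chained mode mitigates but serializes.
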