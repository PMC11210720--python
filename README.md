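# romt

Regularized optimal mass transport (rOMT) for tracking and visualizing
fluid and tracer flows in dynamic 3D images — in particular glymphatic
transport in dynamic contrast-enhanced MRI (DCE-MRI), where serial image
intensity tracks the concentration of an injected tracer moving through
the brain by a mixture of bulk flow (advection) and diffusion.

## The model

Given successive non-negative volumes ρ₀ᵒᵇˢ, ρ₁ᵒᵇˢ, … the solver
recovers, for each adjacent pair, the velocity field
v = (v₀; …; v_{m−1}) minimizing the discrete kinetic-energy objective
with a free (penalized) end point

    min_v  F(v) = ks·kt · ρᵀ M (v ⊙ v) + β ‖ρ_m − ρ₁ᵒᵇˢ‖²
    s.t.   ρ_{i+1} = L⁻¹ S(v_i) ρ_i ,   ρ₀ = ρ₀ᵒᵇˢ

the dynamic (Benamou–Brenier) formulation of optimal transport with the
continuity equation replaced by the advection–diffusion equation
∂ρ/∂t + ∇·(ρv) = σΔρ.  Here S(v) is a mass-conserving particle-in-cell
advection matrix, L = I − kt·Q the backward-Euler step of the diffusion
operator Q ≈ σΔ, M sums squared velocity components per voxel, and β
weighs endpoint fidelity against kinetic energy.  The objective is
minimized by Gauss–Newton with matrix-free Jacobian/Hessian-vector
products, inexact CG inner solves, and a backtracking line search.

The solved (ρ, v) sequence is post-processed in Lagrangian coordinates:
pathlines are traced through the augmented velocity ṽ = v − σ∇log ρ
(under which the dynamics are a pure conservation law), decorated with
speed s = ‖v‖ and Péclet number Pe = ‖v‖/(σ‖∇log ρ‖) — the local ratio
of advective to diffusive transport — rasterized into speed/Pe maps,
and summarized by start-to-end velocity flux vectors.

A fully synthetic test case ships with the package: five frames of a
3D Gaussian sphere whose center drifts while a growing Gaussian filter
emulates diffusion, together with closed-form approximate ground truth
for every intermediate time step and an MSE accuracy harness.  See
`docs/methods.md` for the numerical details and design choices.

## Worked example

Recover the flow between two frames of a Gaussian blob that drifts 1.6
voxels along each axis, then trace pathlines through the result:

```python
import numpy as np
from romt import (GridSpec, ROMTConfig, ROMTProblem, attach_peclet, attach_speed,
                  flux_vectors, seeds_from_volume, trace_pathlines)

grid = GridSpec(16, 16, 16)
X, Y, Z = np.meshgrid(*(np.arange(16),) * 3, indexing="ij")
frame = lambda c: grid.to_flat(np.exp(-((X - c)**2 + (Y - c)**2 + (Z - c)**2) / 8.0))
rho0, rho1 = frame(6.0), frame(7.6)

cfg = ROMTConfig()                       # sigma=0.002, beta=5000, m=10, kt=0.4
prob = ROMTProblem(grid, cfg)
res = prob.solve_pair(rho0, rho1)
first, last = res.cost_history[0], res.cost_history[-1]
print(f"termination: {res.termination} after {len(res.cost_history) - 1} steps")
print(f"fit term:    {first.fit:.1f} -> {last.fit:.1f} "
      f"({100 * last.fit / first.fit:.2f}% of the v=0 baseline)")

seeds = seeds_from_volume(grid.to_volume(rho0), grid, threshold=0.5)
lines = trace_pathlines(seeds, [res], grid, cfg)
attach_speed(lines, [res], grid)
attach_peclet(lines, [res], grid, cfg)
disp = np.mean([f.displacement for f in flux_vectors(lines)], axis=0)
print(f"{len(lines)} pathlines, mean net displacement: "
      f"({disp[0]:.2f}, {disp[1]:.2f}, {disp[2]:.2f}) voxels")
```

Output:

```
termination: max-iter after 20 steps
fit term:    169080.7 -> 163.6 (0.10% of the v=0 baseline)
57 pathlines, mean net displacement: (1.51, 1.51, 1.51) voxels
```

The optimizer drives the endpoint mismatch to 0.1 % of its zero-velocity
baseline, and the pathline flux vectors recover the imposed diagonal
drift (1.51 vs. the true 1.6 voxels per axis; the shortfall is mass that
genuinely arrives by the small diffusive component rather than by
advection).

## Command line

```sh
romt synth --size 25 -o phantom            # emit phantom frames as NIfTI
romt all --size 25 --mode independent -o run   # full pipeline + MSE report
romt solve --frames f0.nii.gz --frames f1.nii.gz --mask mask.nii.gz -o out
romt post out --frame0 f0.nii.gz           # Lagrangian products from a solve
```

`romt solve` accepts every solver parameter as a flag (defaults: m=10,
kt=0.4, ks=1, σ=0.002, β=5000), `--mode chained|independent` to choose
between feeding each loop's final interpolation forward (smoother,
serial) or solving observed frame pairs independently (parallel,
`--jobs N`), and writes velocity fields, interpolations, speed/Pe maps
(NIfTI), pathlines (legacy VTK polydata + CSV), flux vectors and the
per-iteration cost log next to a JSON manifest.

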