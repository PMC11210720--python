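import numpy as np
import pytest

from romt import (
    GridSpec,
    ROMTConfig,
    SolveResult,
    attach_peclet,
    attach_speed,
    augmented_velocity,
    flux_vectors,
    rasterize_lines,
    seeds_from_volume,
    trace_pathlines,
)
from romt.lagrangian import PathlineBundle, sample_field
from romt.solver import CostBreakdown
from romt.transport import DensitySequence


def constant_velocity(grid, m, c):
    n = grid.n
    v = np.empty((m, 3 * n))
    v[:, :n], v[:, n:2 * n], v[:, 2 * n:] = c[0], c[1], c[2]
    return v


def fake_result(grid, m, v, rho0=None, rho=None):
    """Package given fields as a SolveResult for post-processing tests."""
    n = grid.n
    rho0 = np.ones(n) if rho0 is None else rho0
    rho = np.tile(rho0, (m, 1)) if rho is None else rho
    return SolveResult(
        v_star=v,
        interpolations=DensitySequence(rho0=rho0, rho=rho),
        cost_history=[CostBreakdown(0, 0, 0)],
        termination="max-iter",
    )


class TestAugmentedVelocity:
    def test_sigma_zero_returns_velocity(self, rng):
        grid = GridSpec(4, 4, 4)
        v = rng.standard_normal(3 * grid.n)
        rho = rng.uniform(0.1, 1.0, grid.n)
        assert np.array_equal(augmented_velocity(rho, v, 0.0, None, grid), v)

    def test_uniform_density_returns_velocity(self, rng):
        grid = GridSpec(4, 4, 4)
        v = rng.standard_normal(3 * grid.n)
        rho = np.full(grid.n, 2.0)
        assert augmented_velocity(rho, v, 0.5, None, grid) == pytest.approx(v, abs=1e-12)

    def test_exponential_profile_shifts_by_sigma_a(self):
        # rho = exp(a*x): grad log rho = a exactly (central differences
        # are exact for linear log), so v_aug = v - sigma*a in x
        grid = GridSpec(8, 3, 3)
        a, sigma = 0.7, 0.3
        x = np.arange(grid.nx, dtype=float)
        vol = np.exp(a * x)[:, None, None] * np.ones((1, grid.ny, grid.nz))
        rho = grid.to_flat(vol)
        v = np.zeros(3 * grid.n)
        out = augmented_velocity(rho, v, sigma, 1e-300, grid)
        ux = grid.to_volume(out[: grid.n])
        assert ux[1:-1] == pytest.approx(-sigma * a, rel=1e-6)
        assert out[grid.n:] == pytest.approx(0.0, abs=1e-12)


class TestTracePathlines:
    def test_stationary_in_zero_field(self):
        grid = GridSpec(5, 5, 5)
        cfg = ROMTConfig(sigma=0.0, m=3)
        res = fake_result(grid, 3, np.zeros((3, 3 * grid.n)))
        seeds = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        b = trace_pathlines(seeds, [res], grid, cfg)
        assert np.array_equal(b.points[:, 0], seeds)
        for t in range(b.n_steps + 1):
            assert np.array_equal(b.points[:, t], seeds)

    def test_constant_field_euler_is_exact(self):
        grid = GridSpec(12, 12, 12)
        m = 3
        cfg = ROMTConfig(sigma=0.0, m=m, kt=0.4)
        c = np.array([1.0, 0.5, -0.25])
        res = fake_result(grid, m, constant_velocity(grid, m, c))
        seeds = np.array([[4.0, 5.0, 6.0]])
        b = trace_pathlines(seeds, [res], grid, cfg)
        assert b.points[0, -1] == pytest.approx(seeds[0] + m * cfg.kt * c, abs=1e-12)

    def test_out_of_domain_seed_skipped(self):
        grid = GridSpec(4, 4, 4)
        cfg = ROMTConfig(sigma=0.0, m=2)
        res = fake_result(grid, 2, np.zeros((2, 3 * grid.n)))
        seeds = np.array([[1.0, 1.0, 1.0], [9.0, 1.0, 1.0]])
        b = trace_pathlines(seeds, [res], grid, cfg)
        assert len(b) == 1

    def test_trilinear_sampling_exact_at_cell_centers(self, rng):
        grid = GridSpec(4, 5, 6)
        field = rng.standard_normal(grid.n)
        cx, cy, cz = grid.cell_centers()
        pts = np.stack([cx, cy, cz], axis=1).astype(float)
        assert sample_field(field, pts, grid) == pytest.approx(field, abs=1e-13)


class TestSpeedAndPeclet:
    def test_zero_velocity_zero_speed_zero_pe(self):
        grid = GridSpec(4, 4, 4)
        cfg = ROMTConfig(sigma=0.01, m=2)
        res = fake_result(grid, 2, np.zeros((2, 3 * grid.n)),
                          rho0=np.linspace(1, 2, grid.n))
        seeds = np.array([[1.0, 1.0, 1.0]])
        b = trace_pathlines(seeds, [res], grid, cfg)
        attach_speed(b, [res], grid)
        attach_peclet(b, [res], grid, cfg)
        assert np.all(b.speeds == 0.0)
        assert np.all(b.peclets == 0.0)

    def test_constant_345_field_speed_is_5(self):
        grid = GridSpec(10, 10, 10)
        cfg = ROMTConfig(sigma=0.0, m=2, kt=0.01)
        res = fake_result(grid, 2, constant_velocity(grid, 2, (3.0, 4.0, 0.0)))
        b = trace_pathlines(np.array([[2.0, 2.0, 2.0]]), [res], grid, cfg)
        attach_speed(b, [res], grid)
        assert b.speeds == pytest.approx(5.0, abs=1e-12)

    def test_speed_uses_raw_velocity_at_cell_center(self, rng):
        grid = GridSpec(5, 5, 5)
        cfg = ROMTConfig(sigma=0.0, m=1)
        v = rng.standard_normal((1, 3 * grid.n))
        res = fake_result(grid, 1, v)
        seed_idx = (2, 3, 1)
        flat = seed_idx[0] + grid.nx * (seed_idx[1] + grid.ny * seed_idx[2])
        b = trace_pathlines(np.array([seed_idx], dtype=float), [res], grid, cfg)
        attach_speed(b, [res], grid)
        expect = np.sqrt(sum(v[0, c * grid.n + flat] ** 2 for c in range(3)))
        assert b.speeds[0, 0] == pytest.approx(expect, abs=1e-12)

    def test_peclet_closed_form_on_exponential_profile(self):
        # rho = exp(a*x), speed s0 => Pe = s0 / (sigma*|a|) in the interior
        grid = GridSpec(12, 4, 4)
        a, sigma, s0 = 0.5, 0.2, 2.0
        cfg = ROMTConfig(sigma=sigma, m=1, kt=1e-6, eps_log=1e-300)
        x = np.arange(grid.nx, dtype=float)
        vol = np.exp(a * x)[:, None, None] * np.ones((1, grid.ny, grid.nz))
        rho = grid.to_flat(vol)
        v = constant_velocity(grid, 1, (s0, 0.0, 0.0))
        res = fake_result(grid, 1, v, rho0=rho)
        b = trace_pathlines(np.array([[5.0, 2.0, 2.0]]), [res], grid, cfg)
        attach_peclet(b, [res], grid, cfg)
        assert b.peclets[0, 0] == pytest.approx(s0 / (sigma * a), rel=1e-6)

    def test_uniform_density_pe_capped(self):
        grid = GridSpec(5, 5, 5)
        cfg = ROMTConfig(sigma=0.1, m=1, pe_cap=100.0)
        res = fake_result(grid, 1, constant_velocity(grid, 1, (1.0, 0.0, 0.0)))
        b = trace_pathlines(np.array([[2.0, 2.0, 2.0]]), [res], grid, cfg)
        attach_peclet(b, [res], grid, cfg)
        assert b.peclets[0, 0] == cfg.pe_cap

    def test_sigma_zero_peclet_is_an_error(self):
        grid = GridSpec(4, 4, 4)
        cfg = ROMTConfig(sigma=0.0, m=1)
        res = fake_result(grid, 1, np.zeros((1, 3 * grid.n)))
        b = trace_pathlines(np.array([[1.0, 1.0, 1.0]]), [res], grid, cfg)
        with pytest.raises(ValueError, match="Peclet"):
            attach_peclet(b, [res], grid, cfg)


class TestRasterizeAndFlux:
    def make_bundle(self, points, speeds=None, peclets=None):
        b = PathlineBundle(np.asarray(points, dtype=float))
        if speeds is not None:
            b.speeds = np.asarray(speeds, dtype=float)
        if peclets is not None:
            b.peclets = np.asarray(peclets, dtype=float)
        return b

    def test_single_stationary_line_marks_one_voxel(self):
        grid = GridSpec(4, 4, 4)
        pts = np.tile([[1.0, 2.0, 3.0]], (3, 1))[None]     # one line, 2 steps
        b = self.make_bundle(pts, speeds=[[5.0, 5.0]])
        m = rasterize_lines(b, "speed", grid)
        assert m.values[1, 2, 3] == 5.0
        filled = ~np.isnan(m.values)
        assert filled.sum() == 1

    def test_mean_of_samples_in_shared_voxel(self):
        grid = GridSpec(3, 3, 3)
        pts = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                        [[1.1, 0.9, 1.0], [1.0, 1.0, 1.0]]])
        b = self.make_bundle(pts, speeds=[[4.0], [6.0]])
        m = rasterize_lines(b, "speed", grid)
        assert m.values[1, 1, 1] == pytest.approx(5.0)

    def test_matches_dictionary_accumulation_oracle(self, rng):
        grid = GridSpec(5, 6, 4)
        lines, steps = 20, 7
        pts = np.stack([
            rng.uniform(0, grid.nx - 1, (lines, steps + 1)),
            rng.uniform(0, grid.ny - 1, (lines, steps + 1)),
            rng.uniform(0, grid.nz - 1, (lines, steps + 1)),
        ], axis=2)
        vals = rng.uniform(0, 10, (lines, steps))
        b = self.make_bundle(pts, peclets=vals)
        m = rasterize_lines(b, "peclet", grid)
        acc: dict = {}
        for i in range(lines):
            for t in range(steps):
                key = tuple(int(round(c)) for c in pts[i, t])
                acc.setdefault(key, []).append(vals[i, t])
        for key, items in acc.items():
            assert m.values[key] == pytest.approx(np.mean(items))
        assert (~np.isnan(m.values)).sum() == len(acc)

    def test_missing_attribute_rejected(self):
        grid = GridSpec(3, 3, 3)
        b = self.make_bundle(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError):
            rasterize_lines(b, "speed", grid)

    def test_flux_vectors_are_net_displacements(self, rng):
        pts = rng.uniform(0, 5, (6, 4, 3))
        b = self.make_bundle(pts)
        flux = flux_vectors(b)
        for i, fv in enumerate(flux):
            assert np.array_equal(fv.start, pts[i, 0])
            assert fv.displacement == pytest.approx(pts[i, -1] - pts[i, 0])
            assert fv.length == pytest.approx(np.linalg.norm(pts[i, -1] - pts[i, 0]))
        stationary = self.make_bundle(np.ones((1, 3, 3)))
        assert flux_vectors(stationary)[0].length == 0.0


class TestSeeds:
    def test_threshold_and_mask(self):
        grid = GridSpec(3, 3, 3)
        rho = np.zeros(grid.shape)
        rho[0, 0, 0] = 10.0
        rho[1, 1, 1] = 5.0
        rho[2, 2, 2] = 0.5
        seeds = seeds_from_volume(rho, grid, threshold=0.1)
        assert {tuple(s) for s in seeds} == {(0.0, 0.0, 0.0), (1.0, 1.0, 1.0)}
        mask = np.zeros(grid.shape, dtype=bool)
        mask[1, 1, 1] = True
        seeds = seeds_from_volume(rho, grid, threshold=0.1, mask=mask)
        assert {tuple(s) for s in seeds} == {(1.0, 1.0, 1.0)}
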