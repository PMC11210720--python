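"""File I/O: NIfTI volumes, VTK polyline export, CSV tables, run manifests.

Volumes travel as NIfTI (.nii / .nii.gz); phantom runs use an identity
affine and real data keep their input affine on every output.  Pathlines
go out both as legacy ASCII VTK polydata (points + polylines with
per-point speed/Peclet scalars, loadable in ParaView) and as a flat CSV;
flux vectors and cost logs as CSV; the effective config as YAML next to
the outputs so every run is reproducible from its own directory.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import GridSpec
from .lagrangian import FluxVector, PathlineBundle, ScalarMap
from .solver import ROMTConfig, SolveResult


def load_frames(
    paths: list[str | Path],
    mask_path: str | Path | None = None,
    stride: int = 1,
) -> tuple[list[np.ndarray], GridSpec, np.ndarray]:
    """Read a NIfTI frame series (optionally masked and subsampled).

    Negative intensities are clipped to zero (the model transports a
    non-negative density).  If a binary mask is given, the volumes are
    cropped to the mask's bounding box and voxels outside the mask are
    zeroed, shrinking the optimization domain.  ``stride`` keeps every
    k-th frame.  Returns (frames as 3D arrays, grid, affine).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    paths = list(paths)[::stride]
    if not paths:
        raise ValueError("no input frames")
    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{p}: expected a 3D volume, got shape {data.shape}")
        if shape is None:
            shape, affine = data.shape, img.affine
        elif data.shape != shape:
            raise ValueError(f"{p}: shape {data.shape} differs from first frame {shape}")
        vols.append(np.clip(data, 0.0, None))

    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.get_fdata())
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} differs from frames {shape}")
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError(f"mask must be binary (0/1), found values {uniq[:5]}")
        mask = mask.astype(bool)
        if not mask.any():
            raise ValueError("mask is empty")
        lo, hi = [], []
        for ax in range(3):
            proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
            nz = np.nonzero(proj)[0]
            lo.append(nz[0])
            hi.append(nz[-1] + 1)
        box = tuple(slice(lo[a], hi[a]) for a in range(3))
        cropped_mask = mask[box]
        vols = [np.where(cropped_mask, v[box], 0.0) for v in vols]
        shape = vols[0].shape

    grid = GridSpec(*shape)
    return vols, grid, affine if affine is not None else np.eye(4)


def save_nifti(volume: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64),
                             np.eye(4) if affine is None else affine), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_vtk_polylines(bundle: PathlineBundle, path: str | Path) -> None:
    """Legacy ASCII VTK polydata: one polyline per pathline, with optional
    per-point ``speed`` / ``peclet`` scalars (attribute samples pad the
    final point with the last step's value)."""
    npts_per_line = bundle.points.shape[1]
    total = len(bundle) * npts_per_line
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\npathlines\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {total} float\n")
        for line in bundle.points:
            for p in line:
                f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        f.write(f"LINES {len(bundle)} {len(bundle) * (npts_per_line + 1)}\n")
        for i in range(len(bundle)):
            ids = " ".join(str(i * npts_per_line + k) for k in range(npts_per_line))
            f.write(f"{npts_per_line} {ids}\n")
        scalars = [("speed", bundle.speeds), ("peclet", bundle.peclets)]
        scalars = [(name, v) for name, v in scalars if v is not None]
        if scalars:
            f.write(f"POINT_DATA {total}\n")
            for name, vals in scalars:
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                padded = np.concatenate([vals, vals[:, -1:]], axis=1)
                for row in padded:
                    f.write("\n".join(f"{x:.6g}" for x in row) + "\n")


def write_pathline_csv(bundle: PathlineBundle, path: str | Path) -> int:
    """Flat CSV (line_id, step, x, y, z, speed, peclet); returns row count."""
    rows = 0
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["line_id", "step", "x", "y", "z", "speed", "peclet"])
        for i in range(len(bundle)):
            for t in range(bundle.points.shape[1]):
                s = bundle.speeds[i, min(t, bundle.n_steps - 1)] if bundle.speeds is not None else ""
                pe = bundle.peclets[i, min(t, bundle.n_steps - 1)] if bundle.peclets is not None else ""
                p = bundle.points[i, t]
                w.writerow([i, t, f"{p[0]:.6g}", f"{p[1]:.6g}", f"{p[2]:.6g}", s, pe])
                rows += 1
    return rows


def write_flux_csv(vectors: list[FluxVector], path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["x0", "y0", "z0", "dx", "dy", "dz", "length"])
        for v in vectors:
            w.writerow(
                [f"{c:.6g}" for c in (*v.start, *v.displacement)] + [f"{v.length:.6g}"]
            )


def write_cost_log(results: list[SolveResult], path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["loop", "iteration", "energy", "fit", "total", "termination"])
        for loop, res in enumerate(results):
            for it, c in enumerate(res.cost_history):
                w.writerow([loop, it, repr(c.energy), repr(c.fit), repr(c.total),
                            res.termination if it == len(res.cost_history) - 1 else ""])


def save_outputs(
    results: list[SolveResult],
    grid: GridSpec,
    cfg: ROMTConfig,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
    bundle: PathlineBundle | None = None,
    speed_map: ScalarMap | None = None,
    pe_map: ScalarMap | None = None,
    flux: list[FluxVector] | None = None,
    extra: dict | None = None,
) -> dict:
    """Write all artifacts of a run and return the manifest (also saved
    as ``manifest.json``).

    Per loop: the velocity field as a 5D NIfTI of shape (nx, ny, nz, 3, m)
    (component axis before interval axis) and the m interpolations as a
    4D NIfTI.  Plus maps, line exports, flux vectors, cost log and the
    effective config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "n_loops": len(results)}

    def record(key: str, path: Path) -> None:
        manifest["outputs"].setdefault(key, []).append(path.name)

    m = cfg.m
    for loop, res in enumerate(results):
        vel = np.stack(
            [
                np.stack([grid.to_volume(res.v_star[i, c * grid.n:(c + 1) * grid.n])
                          for c in range(3)], axis=3)
                for i in range(m)
            ],
            axis=4,
        )
        p = out / f"velocity_loop{loop}.nii.gz"
        save_nifti(vel, p, affine)
        record("velocity", p)

        interp = np.stack([grid.to_volume(r) for r in res.interpolations.rho], axis=3)
        p = out / f"interpolations_loop{loop}.nii.gz"
        save_nifti(interp, p, affine)
        record("interpolations", p)

    if speed_map is not None:
        p = out / "speed_map.nii.gz"
        save_nifti(speed_map.values, p, affine)
        record("maps", p)
    if pe_map is not None:
        p = out / "pe_map.nii.gz"
        save_nifti(pe_map.values, p, affine)
        record("maps", p)
    if bundle is not None:
        p = out / "pathlines.vtk"
        write_vtk_polylines(bundle, p)
        record("pathlines", p)
        p = out / "pathlines.csv"
        write_pathline_csv(bundle, p)
        record("pathlines", p)
    if flux is not None:
        p = out / "flux_vectors.csv"
        write_flux_csv(flux, p)
        record("flux", p)

    p = out / "cost_log.csv"
    write_cost_log(results, p)
    record("log", p)

    p = out / "config.yaml"
    with open(p, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)
    record("config", p)

    if extra:
        manifest.update(extra)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
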