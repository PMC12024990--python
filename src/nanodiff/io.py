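"""File I/O: geometry and field snapshots (HDF5, legacy-ASCII VTK),
trajectory and MSD tables (CSV), and run provenance.

Every artifact embeds the configuration hash and seeds it was produced from,
so any numeric output can be regenerated from its own metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import GeometrySpec, PorousLattice
from .transport import EnsembleResult, TrajectoryRecord


def config_hash(obj) -> str:
    """Stable short hash of a (nested) dataclass/dict configuration."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# geometry


def save_geometry(path, lattice: PorousLattice, spec: GeometrySpec | None = None) -> None:
    """Write the occupancy grid, spacing and (optionally) the generating spec
    to an HDF5 group."""
    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        g.create_dataset("occupancy", data=lattice.occupancy, compression="gzip")
        g.attrs["spacing"] = lattice.spacing
        g.attrs["porosity"] = lattice.porosity
        if spec is not None:
            g.attrs["spec"] = json.dumps(dataclasses.asdict(spec))
            g.attrs["spec_hash"] = config_hash(spec)


def load_geometry(path) -> tuple[PorousLattice, GeometrySpec | None]:
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        lattice = PorousLattice(g["occupancy"][...], float(g.attrs["spacing"]))
        spec = None
        if "spec" in g.attrs:
            raw = json.loads(g.attrs["spec"])
            for key in ("shape", "tumor_semi_axes"):
                if raw.get(key) is not None:
                    raw[key] = tuple(raw[key])
            spec = GeometrySpec(**raw)
    return lattice, spec


# ---------------------------------------------------------------------------
# VTK (legacy ASCII structured points — plain text, readable by standard
# structured-grid viewers)


def write_vtk_scalars(path, name: str, field: np.ndarray, spacing: float) -> None:
    """Write a 3-D scalar field as a legacy-ASCII VTK STRUCTURED_POINTS file."""
    field = np.asarray(field)
    nx, ny, nz = field.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN 0 0 0\nSPACING {spacing} {spacing} {spacing}\n")
        f.write(f"POINT_DATA {field.size}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x varying fastest
        flat = field.transpose(2, 1, 0).ravel()
        np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")


def write_vtk_geometry(path, lattice: PorousLattice) -> None:
    write_vtk_scalars(path, "occupancy", lattice.occupancy.astype(float), lattice.spacing)


def write_vtk_vectors(path, name: str, field: np.ndarray, spacing: float) -> None:
    """Write a (3, nx, ny, nz) vector field as legacy-ASCII VTK."""
    _, nx, ny, nz = field.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN 0 0 0\nSPACING {spacing} {spacing} {spacing}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write(f"VECTORS {name} float\n")
        flat = field.transpose(0, 3, 2, 1).reshape(3, -1).T
        np.savetxt(f, flat, fmt="%.6g")


# ---------------------------------------------------------------------------
# tables


def trajectories_to_frame(result: EnsembleResult) -> pd.DataFrame:
    """Tidy table: one row per (replicate, particle, sample)."""
    rows = []
    for rep, rec in enumerate(result.records):
        n_s, n_p, _ = rec.positions.shape
        t = np.repeat(rec.times, n_p)
        pid = np.tile(np.arange(n_p), n_s)
        pos = rec.positions.reshape(-1, 3)
        adh = rec.adhered.reshape(-1)
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep, "particle": pid, "t": t,
                    "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                    "adhered": adh,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trajectories_csv(path, result: EnsembleResult) -> None:
    df = trajectories_to_frame(result)
    header = f"# config_hash={config_hash(result.config)} seeds={result.seeds}\n"
    with open(path, "w") as f:
        f.write(header)
        df.to_csv(f, index=False)


def write_msd_csv(path, msd, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "lag": msd.lags,
            "msd_x": msd.msd_axes[0],
            "msd_y": msd.msd_axes[1],
            "msd_z": msd.msd_axes[2],
            "msd_total": msd.msd_total,
        }
    )
    with open(path, "w") as f:
        if meta:
            f.write("# " + json.dumps(meta, default=str) + "\n")
        df.to_csv(f, index=False)


def write_sweep_csv(path, sweeps, meta: dict | None = None) -> None:
    """D table of a sweep: one row per condition."""
    df = pd.DataFrame(
        [
            {
                "label": sw.label,
                "mean_d": sw.mean_d,
                "sd_d": sw.sd_d,
                "n_replicates": len(sw.per_replicate),
                **{k: v for k, v in sw.extra.items() if np.isscalar(v)},
            }
            for sw in sweeps
        ]
    )
    with open(path, "w") as f:
        if meta:
            f.write("# " + json.dumps(meta, default=str) + "\n")
        df.to_csv(f, index=False)


def save_fields_h5(path, lattice: PorousLattice, rho=None, u=None, temperature=None,
                   meta: dict | None = None) -> None:
    """Snapshot of macroscopic fields on the lattice."""
    with h5py.File(path, "w") as f:
        f.attrs["spacing"] = lattice.spacing
        if meta:
            f.attrs["meta"] = json.dumps(meta, default=str)
        f.create_dataset("solid", data=lattice.solid, compression="gzip")
        for name, arr in (("rho", rho), ("u", u), ("temperature", temperature)):
            if arr is not None:
                f.create_dataset(name, data=arr, compression="gzip")


def preflight_writable(paths) -> None:
    """Fail before any computation if an output path cannot be created."""
    for p in paths:
        p = Path(p)
        p.parent.mkdir(parents=True, exist_ok=True)
        try:
            with open(p, "a"):
                pass
        except OSError as exc:
            raise OSError(f"output path {p} is not writable: {exc}") from exc
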