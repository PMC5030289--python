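"""File formats: measurement CSV, profile CSV, HDF5 volumes.

Measurement files are plain CSV with columns ``r_mm, signal_au,
replicate`` (one row per replicate per radius).  Profiles are CSV with
``r_mm`` (or ``z_mm``) and ``phi``.  Label volumes and fluence maps go
to HDF5 with voxel-size/seed metadata, plus a sidecar media table for
grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .geometry import OpticalProperties, VoxelGrid
from .inverse import FitResult, MeasurementSeries
from .transport import RadialProfile, SimulationResult

__all__ = [
    "read_measurement_csv",
    "write_measurement_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_grid_h5",
    "read_grid_h5",
    "write_fluence_h5",
    "write_fit_json",
]


def write_measurement_csv(M: MeasurementSeries, path) -> None:
    rows = []
    if M.replicates is not None:
        for rep_id, rep in enumerate(M.replicates):
            for r, v in zip(M.radii_mm, rep):
                rows.append((r, v, rep_id))
    else:
        rows = [(r, v, 0) for r, v in zip(M.radii_mm, M.signal)]
    pd.DataFrame(rows, columns=["r_mm", "signal_au", "replicate"]).to_csv(
        path, index=False)


def read_measurement_csv(path, label: str = "skeleton") -> MeasurementSeries:
    df = pd.read_csv(path)
    need = {"r_mm", "signal_au", "replicate"}
    if not need.issubset(df.columns):
        raise ValueError(f"measurement CSV needs columns {sorted(need)}")
    wide = df.pivot_table(index="replicate", columns="r_mm",
                          values="signal_au")
    radii = wide.columns.to_numpy(dtype=float)
    reps = wide.to_numpy(dtype=float)
    return MeasurementSeries(radii_mm=radii, signal=reps.mean(axis=0),
                             replicates=reps if reps.shape[0] > 1 else None,
                             label=label)


def write_profile_csv(profile: RadialProfile, path,
                      coord_name: str = "r_mm") -> None:
    cols = {coord_name: profile.radii_mm, "phi": profile.values}
    if profile.stderr is not None:
        cols["mc_stderr"] = profile.stderr
    pd.DataFrame(cols).to_csv(path, index=False)


def read_profile_csv(path, coord_name: str = "r_mm") -> RadialProfile:
    df = pd.read_csv(path)
    return RadialProfile(df[coord_name].to_numpy(), df["phi"].to_numpy(),
                         df["mc_stderr"].to_numpy()
                         if "mc_stderr" in df.columns else None)


def write_grid_h5(grid: VoxelGrid, path, media_csv=None) -> None:
    """Label volume to HDF5; media table inline and optionally as CSV."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=grid.labels, compression="gzip")
        d.attrs["dx_mm"] = grid.dx
        d.attrs["dy_mm"] = grid.dy
        d.attrs["dz_mm"] = grid.dz
        tab = f.create_group("media")
        for lab, p in grid.media.items():
            g = tab.create_group(str(lab))
            for k in ("mu_a", "mu_s", "g", "n"):
                g.attrs[k] = getattr(p, k)
    if media_csv is not None:
        rows = [(lab, p.mu_a, p.mu_s, p.g, p.n)
                for lab, p in sorted(grid.media.items())]
        pd.DataFrame(rows, columns=["label", "mu_a", "mu_s", "g", "n"]
                     ).to_csv(media_csv, index=False)


def read_grid_h5(path) -> VoxelGrid:
    with h5py.File(path, "r") as f:
        d = f["labels"]
        labels = d[...]
        dx, dy, dz = d.attrs["dx_mm"], d.attrs["dy_mm"], d.attrs["dz_mm"]
        media = {}
        for lab, g in f["media"].items():
            media[int(lab)] = OpticalProperties(
                mu_a=float(g.attrs["mu_a"]), mu_s=float(g.attrs["mu_s"]),
                g=float(g.attrs["g"]), n=float(g.attrs["n"]))
    return VoxelGrid(labels=labels, media=media,
                     dx=float(dx), dy=float(dy), dz=float(dz))


def write_fluence_h5(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("fluence", data=result.fluence,
                             compression="gzip")
        d.attrs["units"] = "W cm^-2 per W delivered"
        d.attrs["dx_mm"] = result.grid.dx
        d.attrs["dy_mm"] = result.grid.dy
        d.attrs["dz_mm"] = result.grid.dz
        d.attrs["n_photons"] = result.n_photons
        d.attrs["seed"] = result.seed
        f.create_dataset("escape", data=result.escape, compression="gzip")
        for k, v in result.ledger.items():
            f.attrs[f"ledger_{k}"] = v


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.as_dict(), indent=2))
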