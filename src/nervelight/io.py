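"""Artifact I/O: voxel grids, profiles, sweeps, summaries.

Grids are written as an HDF5 dataset plus a JSON sidecar carrying the
origin, voxel size and the configuration hash; optionally also as a
multi-page TIFF stack of z-slices for quick inspection.  Tabular outputs
(profiles, sweeps) are CSV with the config hash embedded in a header
comment so mismatched bundles are detectable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .transport import VoxelGrid

__all__ = [
    "config_hash",
    "save_grid",
    "load_grid",
    "save_tiff_stack",
    "save_profile_csv",
    "save_sweep_csv",
    "save_summary_json",
    "read_embedded_hash",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def save_grid(grid: VoxelGrid, path, config: dict | None = None) -> None:
    """Write a grid as HDF5 (`values` dataset) with a JSON sidecar."""
    import h5py

    path = Path(path)
    meta = {
        "origin_mm": list(map(float, grid.origin)),
        "voxel_size_mm": grid.voxel_size,
        "dims": list(grid.dims),
        "skipped_samples": int(grid.skipped_samples),
        "config_hash": config_hash(config or {}),
    }
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=grid.values, compression="gzip")
        for k, v in meta.items():
            d.attrs[k] = json.dumps(v) if isinstance(v, list) else v
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def load_grid(path) -> VoxelGrid:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["values"]
        origin = json.loads(d.attrs["origin_mm"])
        voxel = float(d.attrs["voxel_size_mm"])
        values = d[...]
    grid = VoxelGrid(origin, voxel, values.shape)
    grid.values = values
    return grid


def save_tiff_stack(grid: VoxelGrid, path) -> None:
    """Write the grid as a multi-page float32 TIFF, one page per z-slice."""
    import tifffile

    stack = np.moveaxis(grid.values, 2, 0).astype(np.float32)
    tifffile.imwrite(path, stack)


def save_profile_csv(profile, path, config: dict | None = None) -> None:
    """Ring profile as CSV: ring_center_mm, ring_max, normalized columns."""
    norm = profile.normalized("surface=1")
    rel = profile.normalized("surface-relative-%")
    header = (
        f"# config_hash={config_hash(config or {})}\n"
        "ring_center_mm,ring_max,surface_normalized,percent_vs_surface"
    )
    data = np.column_stack(
        [profile.ring_centers, profile.ring_max, norm.ring_max, rel.ring_max]
    )
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.10g")


def save_sweep_csv(sweep, path, config: dict | None = None) -> None:
    """Sweep as CSV: parameter value, focal gain percent."""
    header = (
        f"# config_hash={config_hash(config or {})}\n"
        f"{sweep.parameter},focal_gain_percent"
    )
    data = np.column_stack([sweep.values, sweep.focal_gain_percent])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.10g")


def save_summary_json(summary: dict, path, config: dict | None = None) -> None:
    out = dict(summary)
    out["config_hash"] = config_hash(config or {})
    Path(path).write_text(json.dumps(out, indent=2, default=str) + "\n")


def read_embedded_hash(path) -> str | None:
    """Recover the config hash embedded in a CSV header or summary JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text).get("config_hash")
    for line in text.splitlines():
        if line.startswith("# config_hash="):
            return line.split("=", 1)[1].strip()
    return None
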