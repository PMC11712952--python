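"""Voxel-grid and table round-tripping plus run configuration.

Voxel maps travel as MetaImage (.mhd header + .raw payload) through
SimpleITK, with the grid origin/spacing carried in the header; histograms
and tables as CSV.  A run configuration is a YAML mapping with explicit
seeds; unknown keys are rejected so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from dcslet.scoring import ScoreMaps, VoxelGrid


def write_voxel_grid(path, array: np.ndarray, grid: VoxelGrid) -> None:
    """Write a (nx, ny, nz) array as MetaImage; NaNs pass through."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(array, (2, 1, 0)).astype(np.float64)))
    img.SetOrigin(tuple(grid.origin))
    img.SetSpacing(tuple(grid.spacing))
    sitk.WriteImage(img, str(path))


def read_voxel_grid(path):
    """Read a MetaImage written by :func:`write_voxel_grid`.

    Returns (array, grid); origin and spacing are restored from the header.
    """
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"malformed voxel-grid file {path}: {exc}") from exc
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    grid = VoxelGrid(origin=img.GetOrigin(), spacing=img.GetSpacing(),
                     dims=arr.shape)
    return arr, grid


def write_scoremaps(prefix, maps: ScoreMaps) -> None:
    """One MetaImage per accumulator: <prefix>_{sum_e,...}.mhd."""
    for name in ("sum_e", "sum_l", "sum_e2_over_l", "sum_e_point"):
        write_voxel_grid(f"{prefix}_{name}.mhd", getattr(maps, name), maps.grid)


def read_scoremaps(prefix) -> ScoreMaps:
    arrays = {}
    grid = None
    for name in ("sum_e", "sum_l", "sum_e2_over_l", "sum_e_point"):
        arrays[name], grid = read_voxel_grid(f"{prefix}_{name}.mhd")
    return ScoreMaps(grid, arrays["sum_e"], arrays["sum_l"],
                     arrays["sum_e2_over_l"], arrays["sum_e_point"])


def write_histogram_csv(path, bin_left: np.ndarray, counts: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([bin_left, counts]), delimiter=",",
               header="bin_left,count", comments="")


_KNOWN_KEYS = {
    "energy", "energies", "scenario", "offset_cm", "offsets_cm", "histories",
    "seed", "target", "collimation_strategy", "prescription",
    "energy_spacing", "spot_spacing", "normal_penalty", "nuclear_on",
    "straggling_on", "scattering_on", "grid_dims", "grid_spacing",
    "grid_origin", "rbe", "out_dir",
}


def load_config(path) -> dict:
    """Load a YAML run config; unknown keys raise."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamps."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
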