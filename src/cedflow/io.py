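"""NIfTI volume I/O and YAML run configuration."""

from __future__ import annotations

import copy
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import ScalarField, VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "grid_from_affine",
    "load_config",
    "dump_config",
    "default_config",
]


def grid_from_affine(shape, affine: np.ndarray) -> VoxelGrid:
    affine = np.asarray(affine, dtype=float)
    spacing = tuple(float(np.linalg.norm(affine[:3, k])) for k in range(3))
    origin = tuple(float(x) for x in affine[:3, 3])
    return VoxelGrid(tuple(int(n) for n in shape), spacing, origin, affine=affine)


def read_volume(
    path, units: str = "", expected_grid: VoxelGrid | None = None
) -> ScalarField:
    """Read a (possibly gzipped) NIfTI volume into a ScalarField.

    Raises ``ValueError`` naming both geometries if the volume does not sit
    on ``expected_grid``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = grid_from_affine(data.shape, img.affine)
    if expected_grid is not None and not grid.same_geometry(expected_grid):
        raise ValueError(
            f"{path}: grid mismatch — file has shape {grid.shape} / affine\n"
            f"{grid.affine}\nexpected shape {expected_grid.shape} / affine\n"
            f"{expected_grid.affine}"
        )
    return ScalarField(grid, data, units=units)


def write_volume(field: ScalarField, path) -> Path:
    """Write a ScalarField as NIfTI (float64, so values round-trip bit-exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(field.values.astype(np.float64), field.grid.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "use": True,
        "compact": True,
    },
    "tissue": {
        "adc_normal": 0.77e-5,
        "adc_csf": 2.6e-5,
        "phi_normal": 0.2,
        "phi_min": 0.05,
        "K_ref": 2.0e-7,
        "beta2_ref": 1.0e-7,
        "gray": {"alpha": 0.7, "B_drained": 5000.0, "G_shear": 1000.0},
        "white": {"alpha": 0.99, "B_drained": 500.0, "G_shear": 1000.0},
        "tumor": {"alpha": 0.7, "B_drained": 5000.0, "G_shear": 1000.0},
    },
    "flow": {"max_iter": 10, "tol": 1.0e-3},
    "transport": {
        "molecule": "gd_dtpa",
        "molecular_weight_ratio": 52.0,  # Gd-DTPA (~938 Da) vs water
        "diffusion_off": False,
        "uniform_loss": None,
        "water_diffusivity": 7.7e-4,  # mm^2/s in tissue
    },
    "protocol": {
        "duration_h": 24.0,
        "snapshot_times_h": [24.0],
        "flow_rate_mL_h": 0.5,
        "infusate_concentration": 1.0,
    },
    "quantify": {"threshold_fraction": 0.1, "r1": 3.7},
    "dce": {"normal_loss_rate": 1.0e-6},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML run config, filled in with package defaults.

    Referenced input volumes (when the phantom is not used) must exist.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    inputs = cfg.get("inputs", {})
    if not cfg["phantom"]["use"]:
        for key in ("tissue_map", "adc"):
            p = inputs.get(key)
            if p is None or not Path(p).exists():
                raise ValueError(f"config input '{key}' missing or file not found: {p}")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
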