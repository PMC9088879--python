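"""Standard-format I/O: NIfTI volumes, centerline CSVs, cohort CSVs, YAML."""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib
import yaml

from .geometry import Centerline, GeometryError, VoxelGrid
from .synthetic import MANDATORY_COLUMNS


class IOError_(ValueError):
    """Malformed or incomplete file."""


def write_volume(grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(grid.data.astype(np.float32), grid.affine)
    nib.save(img, str(path))


def read_volume(path) -> VoxelGrid:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError_(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError_(f"expected a 3D image, got {data.ndim}D")
    aff = img.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    return VoxelGrid(data.astype(np.float64), spacing, aff[:3, 3].copy())


def write_mask(mask: np.ndarray, like: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), like.affine)
    nib.save(img, str(path))


def write_centerline(cl: Centerline, path) -> None:
    df = pd.DataFrame(
        {
            "x": cl.points[:, 0],
            "y": cl.points[:, 1],
            "z": cl.points[:, 2],
            "s": cl.arc,
            "tx": cl.tangents[:, 0],
            "ty": cl.tangents[:, 1],
            "tz": cl.tangents[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_centerline(path) -> Centerline:
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise IOError_(f"centerline CSV missing columns: {sorted(missing)}")
    return Centerline.from_points(df[["x", "y", "z"]].to_numpy())


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"cohort CSV missing mandatory columns: {missing}")
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
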