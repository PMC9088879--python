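"""Peri-stent perivascular fat attenuation index (FAI).

The perivascular adipose tissue (PVAT) around a stented coronary segment is
defined geometrically: all voxels whose centers lie within a radial band
outside the stent surface — inner radius R = stent diameter / 2 from the
centerline, thickness D = multiplier x stent diameter (multiplier 1 by
default, i.e. a band one stent-diameter thick, the standard PVAT
definition) — and whose nearest arc position falls within the stent's
longitudinal extent (optionally extended by the 5 mm edge segments used in
the restenosis definition).

The FAI is the mean attenuation of shell voxels inside the adipose window
of -190 to -30 HU (inclusive); less negative values indicate the
inflammation-associated shift from the lipid toward the aqueous phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Centerline, GeometryError, StentAnnotation, VoxelGrid


class FAIError(ValueError):
    """Unusable FAI measurement (empty shell, no adipose voxels)."""


@dataclass
class FAIConfig:
    """HU window and shell-geometry rules for the FAI measurement."""

    window_low: float = -190.0  # HU, inclusive
    window_high: float = -30.0  # HU, inclusive
    radial_multiplier: float = 1.0  # shell thickness = multiplier * stent diameter
    longitudinal_extent: str = "stent"  # "stent" | "stent±5mm"
    edge_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if not self.window_low < self.window_high:
            raise FAIError("window low must be below window high")
        if self.radial_multiplier <= 0:
            raise FAIError("radial multiplier must be positive")
        if self.longitudinal_extent not in {"stent", "stent±5mm"}:
            raise FAIError(f"unknown longitudinal extent {self.longitudinal_extent!r}")


@dataclass
class FAIMeasurement:
    """Mean in-window shell attenuation plus the voxel bookkeeping."""

    fai_hu: float
    n_shell_voxels: int
    n_window_voxels: int
    in_window_fraction: float
    shell_volume_mm3: float


def build_pvat_shell(
    grid: VoxelGrid,
    centerline: Centerline,
    annotation: StentAnnotation,
    config: FAIConfig = None,
) -> np.ndarray:
    """Boolean mask of the peri-stent perivascular shell.

    A voxel belongs to the shell iff its center's orthogonal projection onto
    the centerline lands within the longitudinal extent and its radial
    distance r satisfies ``R < r <= R + D`` with R = stent radius and
    D = multiplier x stent diameter. Voxels at or inside the stent surface
    are never included.
    """
    config = config or FAIConfig()
    lo, hi = annotation.start_mm, annotation.end_mm
    if config.longitudinal_extent == "stent±5mm":
        lo, hi = lo - config.edge_margin_mm, hi + config.edge_margin_mm
    lo = max(lo, 0.0)
    hi = min(hi, centerline.length)
    if not hi > lo:
        raise GeometryError("empty longitudinal extent for the PVAT shell")
    if annotation.start_mm > centerline.length or annotation.end_mm < 0:
        raise GeometryError("stent extent outside the centerline arc range")

    R = annotation.diameter_mm / 2.0
    D = config.radial_multiplier * annotation.diameter_mm
    centers = grid.voxel_centers().reshape(-1, 3)
    s, r = centerline.nearest(centers)
    mask = (s >= lo) & (s <= hi) & (r > R) & (r <= R + D)
    if not mask.any():
        raise FAIError("perivascular shell is empty on this grid")
    return mask.reshape(grid.dims)


def compute_fai(
    volume: VoxelGrid, shell_mask: np.ndarray, config: FAIConfig = None
) -> FAIMeasurement:
    """Mean HU of shell voxels inside the adipose window.

    Lumen contrast and stent struts fall outside the window and are excluded
    automatically; an empty in-window set raises (unusable measurement, as
    with artifact-corrupted stents).
    """
    config = config or FAIConfig()
    shell_mask = np.asarray(shell_mask, dtype=bool)
    if shell_mask.shape != volume.dims:
        raise GeometryError("shell mask not aligned to volume")
    shell_hu = volume.data[shell_mask]
    inwin = (shell_hu >= config.window_low) & (shell_hu <= config.window_high)
    n_win = int(inwin.sum())
    if n_win == 0:
        raise FAIError("no adipose voxels in the HU window")
    n_shell = int(shell_mask.sum())
    return FAIMeasurement(
        fai_hu=float(shell_hu[inwin].mean()),
        n_shell_voxels=n_shell,
        n_window_voxels=n_win,
        in_window_fraction=n_win / n_shell,
        shell_volume_mm3=float(n_shell * np.prod(volume.spacing)),
    )


def measure_peristent_fai(
    volume: VoxelGrid,
    centerline: Centerline,
    annotation: StentAnnotation,
    config: FAIConfig = None,
) -> FAIMeasurement:
    """Build the peri-stent shell and compute the FAI in one step."""
    config = config or FAIConfig()
    shell = build_pvat_shell(volume, centerline, annotation, config)
    return compute_fai(volume, shell, config)
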