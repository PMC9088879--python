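"""Synthetic CT phantoms and patient cohorts with known ground truth.

The phantom generator builds a contrast-filled vessel (straight or helical)
carrying a stent, wrapped in a perivascular fat compartment, on a regular
voxel grid; every voxel is classified by the distance of its *center* from
the analytic centerline (no partial-volume weighting), so downstream
geometric measurements can be validated against exact truth masks.

The cohort generator draws per-patient covariates from the group-wise
summary statistics of the study population it emulates (ISR vs non-ISR
groups of a coronary-stent cohort): binary covariates are Bernoulli,
continuous covariates Normal, and within the ISR group the restenosis
degree and the peri-stent fat attenuation index (FAI) are coupled through
a Gaussian copula at a configurable Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import Centerline, GeometryError, StentAnnotation, VoxelGrid


class SyntheticError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

FAT_WINDOW = (-190.0, -30.0)  # adipose HU window


@dataclass
class PhantomConfig:
    """Geometry and attenuation parameters of a stented-vessel CT phantom.

    Defaults describe a 4.2 mm diameter, 28 mm long stent (the cohort means)
    in a straight vessel on an isotropic 0.5 mm grid. HU levels: contrast
    lumen 350, stent struts 800, vessel wall / neointima 60, background
    soft tissue N(40, 10), perivascular fat N(fat_mean, fat_sd) sampled
    i.i.d. per voxel.
    """

    dims: tuple[int, int, int] = (40, 40, 100)
    spacing_mm: float = 0.5
    curve: str = "straight"  # straight | helical
    axis: str = "z"  # straight curves only
    helix_radius_mm: float = 5.0
    helix_pitch_mm: float = 80.0
    lumen_radius_mm: float = 1.65
    wall_thickness_mm: float = 0.45
    strut_thickness_mm: float = 0.25
    strut_ring_pitch_mm: float = 1.5  # longitudinal spacing of strut rings
    strut_ring_width_mm: float = 0.3
    stent_start_mm: float = 11.0
    stent_end_mm: float = 39.0
    strut_attenuation: float = 800.0
    lumen_attenuation: float = 350.0
    wall_attenuation: float = 60.0
    background_mean: float = 40.0
    background_sd: float = 10.0
    fat_mean: float = -87.2
    fat_sd: float = 7.3
    fat_fraction: float = 1.0  # perivascular voxels drawn from fat vs contaminant
    contaminant_mean: float = 15.0
    contaminant_sd: float = 10.0
    fat_outer_radius_mm: Optional[float] = None  # default 1.55 * stent diameter
    stenosis_fraction: float = 0.0  # fractional diameter loss at worst point
    stenosis_center_mm: Optional[float] = None  # default mid-stent
    stenosis_length_mm: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise SyntheticError("spacing must be positive")
        if self.lumen_radius_mm <= 0:
            raise SyntheticError("lumen radius must be positive")
        if self.wall_thickness_mm < 0 or self.strut_thickness_mm < 0:
            raise SyntheticError("thicknesses must be non-negative")
        if self.curve not in {"straight", "helical"}:
            raise SyntheticError(f"unknown curve kind {self.curve!r}")
        if self.curve == "straight" and self.axis not in {"x", "y", "z"}:
            raise SyntheticError(f"unknown axis {self.axis!r}")
        if not self.stent_end_mm > self.stent_start_mm:
            raise SyntheticError("stent end must exceed start")
        if not 0.0 <= self.stenosis_fraction < 1.0:
            raise SyntheticError("stenosis fraction must lie in [0, 1)")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise SyntheticError("fat fraction must lie in [0, 1]")
        if self.fat_sd < 0 or self.background_sd < 0 or self.noise_sd < 0:
            raise SyntheticError("standard deviations must be non-negative")

    @property
    def stent_radius_mm(self) -> float:
        """Outer stent radius: lumen plus wall (stent apposed to outer wall)."""
        return self.lumen_radius_mm + self.wall_thickness_mm

    @property
    def stent_diameter_mm(self) -> float:
        return 2.0 * self.stent_radius_mm

    @property
    def fat_outer_mm(self) -> float:
        if self.fat_outer_radius_mm is not None:
            return self.fat_outer_radius_mm
        return 1.55 * self.stent_diameter_mm


@dataclass
class PhantomTruth:
    """Noise-free ground truth accompanying a generated phantom."""

    centerline: Centerline
    lumen_mask: np.ndarray
    stent_mask: np.ndarray
    shell_mask: np.ndarray  # perivascular shell: R < r <= R + D over the stent
    fat_mean: float
    fat_sd: float
    minimal_stent_diameter_mm: float
    reference_diameter_mm: float
    annotation: StentAnnotation = None


def _analytic_curve(cfg: PhantomConfig, fine_step: float = 0.05):
    """Finely sampled analytic centerline points and arc lengths."""
    sp = cfg.spacing_mm
    extent = (np.asarray(cfg.dims) - 1) * sp
    center = extent / 2.0
    if cfg.curve == "straight":
        ax = "xyz".index(cfg.axis)
        length = extent[ax]
        s = np.arange(0.0, length + fine_step / 2, fine_step)
        pts = np.tile(center, (len(s), 1))
        pts[:, ax] = s
        return pts, s, length
    # helix around the central z axis, ostium at z = 0
    r, pitch = cfg.helix_radius_mm, cfg.helix_pitch_mm
    c = pitch / (2 * np.pi)
    speed = np.hypot(r, c)
    length = extent[2] * speed / c  # fill the z extent
    s = np.arange(0.0, length + fine_step / 2, fine_step)
    theta = s / speed
    pts = np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta), c * theta]
    )
    return pts, s, length


def _lumen_radius_profile(cfg: PhantomConfig, s: np.ndarray) -> np.ndarray:
    """Lumen radius vs arc length, with an optional cosine-bump stenosis."""
    radius = np.full_like(s, cfg.lumen_radius_mm, dtype=float)
    if cfg.stenosis_fraction > 0:
        s0 = cfg.stenosis_center_mm
        if s0 is None:
            s0 = 0.5 * (cfg.stent_start_mm + cfg.stent_end_mm)
        half = cfg.stenosis_length_mm / 2.0
        inside = np.abs(s - s0) <= half
        bump = 0.5 * (1 + np.cos(np.pi * (s[inside] - s0) / half))
        radius[inside] *= 1.0 - cfg.stenosis_fraction * bump
    return radius


def generate_phantom(cfg: PhantomConfig) -> tuple[VoxelGrid, PhantomTruth]:
    """Voxelize a stented-vessel phantom with exact truth masks.

    Each voxel is assigned a tissue class by the radial distance of its
    center from the analytic centerline (voxel-center rule); additive
    Gaussian image noise is applied last, and truth masks are noise-free.
    """
    sp = cfg.spacing_mm
    pts_fine, s_fine, length = _analytic_curve(cfg)
    if cfg.stent_end_mm > length + 1e-9 or cfg.stent_start_mm < -1e-9:
        raise SyntheticError(
            f"stent extent [{cfg.stent_start_mm}, {cfg.stent_end_mm}] outside "
            f"curve length {length:.1f} mm"
        )
    shell_outer = cfg.stent_radius_mm + cfg.stent_diameter_mm
    extent = (np.asarray(cfg.dims) - 1) * sp
    in_stent = (s_fine >= cfg.stent_start_mm) & (s_fine <= cfg.stent_end_mm)
    tan_fine = np.gradient(pts_fine, s_fine, axis=0)
    tan_fine /= np.linalg.norm(tan_fine, axis=1, keepdims=True)
    # a disk of radius shell_outer perpendicular to the tangent extends
    # shell_outer*sqrt(1-t_a^2) along axis a
    need = shell_outer * np.sqrt(
        np.clip(1.0 - tan_fine[in_stent] ** 2, 0.0, 1.0)
    )
    margins = np.minimum(pts_fine[in_stent], extent - pts_fine[in_stent])
    if (margins < need - 1e-9).any():
        raise SyntheticError(
            "grid too small: perivascular shell extends outside the volume"
        )

    grid_shape = tuple(cfg.dims)
    spacing = np.full(3, sp)
    axes = [np.arange(n) * sp for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    if cfg.curve == "straight":
        ax = "xyz".index(cfg.axis)
        others = [a for a in range(3) if a != ax]
        ctr = (np.asarray(grid_shape) - 1) * sp / 2.0
        r = np.hypot(
            centers[:, others[0]] - ctr[others[0]],
            centers[:, others[1]] - ctr[others[1]],
        )
        s = np.clip(centers[:, ax], 0.0, length)
    else:
        from .geometry import _project_to_polyline

        s, r = _project_to_polyline(pts_fine, s_fine, centers)

    lum_r = _lumen_radius_profile(cfg, s)
    stent_in = (s >= cfg.stent_start_mm) & (s <= cfg.stent_end_mm)
    R = cfg.stent_radius_mm

    lumen = r <= lum_r
    # struts form sparse rings (stents are wire meshes, not solid tubes);
    # between rings the band at the stent surface is vessel wall
    on_ring = np.mod(s - cfg.stent_start_mm, cfg.strut_ring_pitch_mm) < (
        cfg.strut_ring_width_mm
    )
    stent = (
        stent_in
        & on_ring
        & (r > R - cfg.strut_thickness_mm)
        & (r <= R)
        & ~lumen
    )
    wall = ~lumen & ~stent & (r <= R)
    fat_zone = (r > R) & (r <= cfg.fat_outer_mm)
    shell = stent_in & (r > R) & (r <= R + cfg.stent_diameter_mm)

    rng = np.random.default_rng(cfg.seed)
    hu = np.empty(len(centers))
    hu[lumen] = cfg.lumen_attenuation
    hu[stent] = cfg.strut_attenuation
    hu[wall] = cfg.wall_attenuation
    nfat = int(fat_zone.sum())
    fat_vals = rng.normal(cfg.fat_mean, cfg.fat_sd, size=nfat)
    if cfg.fat_fraction < 1.0:
        contam = rng.random(nfat) >= cfg.fat_fraction
        fat_vals[contam] = rng.normal(
            cfg.contaminant_mean, cfg.contaminant_sd, size=int(contam.sum())
        )
    hu[fat_zone] = fat_vals
    bg = ~(lumen | stent | wall | fat_zone)
    hu[bg] = rng.normal(cfg.background_mean, cfg.background_sd, size=int(bg.sum()))
    if cfg.noise_sd > 0:
        hu += rng.normal(0.0, cfg.noise_sd, size=hu.shape)

    volume = VoxelGrid(hu.reshape(grid_shape), spacing)
    coarse = Centerline.from_points(pts_fine).resample(0.5)
    in_stent_fine = (s_fine >= cfg.stent_start_mm) & (s_fine <= cfg.stent_end_mm)
    d_min = 2.0 * float(_lumen_radius_profile(cfg, s_fine)[in_stent_fine].min())
    annotation = StentAnnotation(
        vessel="LAD",
        segment="middle",
        start_mm=cfg.stent_start_mm,
        end_mm=cfg.stent_end_mm,
        diameter_mm=cfg.stent_diameter_mm,
    )
    truth = PhantomTruth(
        centerline=coarse,
        lumen_mask=lumen.reshape(grid_shape),
        stent_mask=stent.reshape(grid_shape),
        shell_mask=shell.reshape(grid_shape),
        fat_mean=cfg.fat_mean,
        fat_sd=cfg.fat_sd,
        minimal_stent_diameter_mm=d_min,
        reference_diameter_mm=2.0 * cfg.lumen_radius_mm,
        annotation=annotation,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Group-wise parameters (non-ISR, ISR) emulating the study population.
# Binary covariates: probability per group.
DEFAULT_BINARY: dict[str, tuple[float, float]] = {
    "male": (44 / 65, 39 / 52),
    "hyperlipidemia": (17 / 65, 15 / 52),
    "diabetes": (22 / 65, 18 / 52),
    "hypertension": (31 / 65, 28 / 52),
    "smoking": (23 / 65, 21 / 52),
    "prior_mi": (8 / 65, 12 / 52),
    "des": (58 / 65, 43 / 52),
}

# Continuous covariates: (mean, sd) per group, units fixed per key.
DEFAULT_CONTINUOUS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age_years": ((66.2, 9.9), (68.0, 11.0)),
    "hemoglobin_g_l": ((135.3, 14.1), (131.0, 22.2)),
    "total_bilirubin_umol_l": ((10.8, 4.5), (11.2, 4.9)),
    "direct_bilirubin_umol_l": ((3.0, 1.4), (3.4, 1.8)),
    "indirect_bilirubin_umol_l": ((7.8, 3.7), (7.7, 3.4)),
    "creatinine_umol_l": ((75.4, 14.2), (83.6, 32.0)),
    "cpk_u_l": ((93.6, 38.3), (117.0, 72.3)),
    "bnp_pg_ml": ((65.2, 46.1), (199.5, 495.1)),
    "total_cholesterol_mmol_l": ((3.5, 0.9), (3.5, 0.9)),
    "hdl_c_mmol_l": ((1.3, 0.3), (1.2, 0.2)),
    "ldl_c_mmol_l": ((2.0, 0.7), (2.0, 0.8)),
    "tg_mmol_l": ((1.6, 1.0), (1.4, 0.8)),
    "apoa1_g_l": ((1.2, 0.2), (1.1, 0.2)),
    "apob_g_l": ((0.7, 0.2), (0.7, 0.3)),
    "apoe_mg_dl": ((3.6, 1.4), (3.3, 1.1)),
    "platelet_10e9_l": ((183.7, 43.5), (188.5, 63.3)),
    "erythrocytes_10e9_l": ((4.4, 0.4), (4.3, 0.6)),
    "leucocytes_10e9_l": ((6.0, 1.6), (6.4, 2.0)),
    "rdw_pct": ((12.9, 0.9), (13.4, 1.8)),
    "lymphocytes_10e9_l": ((1.7, 0.7), (1.7, 0.7)),
    "neutrophils_10e9_l": ((3.5, 1.2), (3.9, 1.6)),
    "monocytes_10e9_l": ((0.5, 0.2), (0.5, 0.2)),
    "hs_crp_mg_l": ((2.8, 3.6), (4.6, 6.6)),
    "hba1c_pct": ((6.4, 1.2), (6.6, 1.1)),
    "stent_length_mm": ((28.0, 12.1), (28.0, 9.8)),
    "stent_diameter_mm": ((4.2, 0.5), (4.2, 0.5)),
    "months_since_pci": ((37.09, 14.70), (33.85, 14.12)),
}

# Vessel location counts per group (LAD, LCx, RCA).
DEFAULT_VESSEL_PROPS: dict[str, tuple[float, float]] = {
    "LAD": (40 / 65, 33 / 52),
    "LCx": (9 / 65, 11 / 52),
    "RCA": (16 / 65, 8 / 52),
}

DEFAULT_SEGMENT_PROPS: dict[str, tuple[float, float]] = {
    "proximal": (26 / 65, 25 / 52),
    "middle": (36 / 65, 24 / 52),
    "distal": (3 / 65, 3 / 52),
}


@dataclass
class CohortConfig:
    """Distributional parameters of a synthetic stented-patient cohort."""

    n_isr: int = 52
    n_nonisr: int = 65
    fai_mean: tuple[float, float] = (-87.2, -78.1)  # (non-ISR, ISR), HU
    fai_sd: tuple[float, float] = (7.3, 6.2)
    degree_mean: float = 50.3  # % diameter stenosis, ISR group
    degree_sd: float = 21.5
    degree_fai_corr: float = 0.579  # Pearson target within the ISR group
    binary: dict = field(default_factory=lambda: dict(DEFAULT_BINARY))
    continuous: dict = field(default_factory=lambda: dict(DEFAULT_CONTINUOUS))
    vessel_props: dict = field(default_factory=lambda: dict(DEFAULT_VESSEL_PROPS))
    segment_props: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_PROPS))
    rater_noise_sd: float = 0.85  # HU, per-observer measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isr < 0 or self.n_nonisr < 0:
            raise SyntheticError("group sizes must be non-negative")
        if not abs(self.degree_fai_corr) < 1.0:
            raise SyntheticError("|correlation| must be < 1")
        if min(self.fai_sd) < 0 or self.degree_sd < 0 or self.rater_noise_sd < 0:
            raise SyntheticError("standard deviations must be non-negative")
        for name, (p0, p1) in self.binary.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise SyntheticError(f"proportion out of [0,1] for {name!r}")


MANDATORY_COLUMNS = ("id", "isr", "peri_stent_fai_hu")


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table, deterministic under a fixed seed.

    Within the ISR group, (degree of ISR, FAI) pairs are bivariate normal at
    the configured correlation, with the degree clipped to [0, 100] %
    (Gaussian copula; clipping affects < 2 % of the mass at the default
    parameters). Two simulated observer readings of the FAI are included
    for inter-rater analysis.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, n in ((0, cfg.n_nonisr), (1, cfg.n_isr)):
        fai_mu, fai_sd = cfg.fai_mean[group], cfg.fai_sd[group]
        if group == 1:
            rho = cfg.degree_fai_corr
            cov = [[1.0, rho], [rho, 1.0]]
            z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
            degree = np.clip(cfg.degree_mean + cfg.degree_sd * z[:, 0], 0.0, 100.0)
            fai = fai_mu + fai_sd * z[:, 1]
        else:
            degree = np.full(n, np.nan)
            fai = rng.normal(fai_mu, fai_sd, size=n)
        vessels = rng.choice(
            list(cfg.vessel_props),
            size=n,
            p=_norm_probs([v[group] for v in cfg.vessel_props.values()]),
        )
        segments = rng.choice(
            list(cfg.segment_props),
            size=n,
            p=_norm_probs([v[group] for v in cfg.segment_props.values()]),
        )
        rec = {
            "isr": np.full(n, group),
            "peri_stent_fai_hu": fai,
            "degree_of_isr_pct": degree,
            "vessel": vessels,
            "segment": segments,
        }
        for name, probs in cfg.binary.items():
            rec[name] = (rng.random(n) < probs[group]).astype(int)
        for name, params in cfg.continuous.items():
            mu, sd = params[group]
            rec[name] = rng.normal(mu, sd, size=n)
        rec["fai_rater1_hu"] = fai + rng.normal(0, cfg.rater_noise_sd, size=n)
        rec["fai_rater2_hu"] = fai + rng.normal(0, cfg.rater_noise_sd, size=n)
        rows.append(pd.DataFrame(rec))
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "id", [f"P{i + 1:03d}" for i in range(len(df))])
    df["stent_class"] = np.where(df["des"] == 1, "DES", "BMS")
    return df


def _norm_probs(p):
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise SyntheticError("negative category proportion")
    return p / p.sum()


def percent(count: float, total: float, digits: int = 1) -> float:
    """Percentage as printed in cohort tables, e.g. percent(44, 65) -> 67.7."""
    if total <= 0:
        raise SyntheticError("total must be positive")
    return round(100.0 * count / total, digits)
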