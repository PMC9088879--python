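import numpy as np
import pytest

import stentfai as sf


@pytest.fixture(scope="session")
def straight_phantom():
    """Default straight-vessel phantom (no noise, no stenosis)."""
    cfg = sf.PhantomConfig(seed=1)
    vol, truth = sf.generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def straight_centerline(straight_phantom):
    cfg, vol, truth = straight_phantom
    return sf.extract_centerline(truth.lumen_mask, vol.spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """Small grid (32^3) suitable for exhaustive brute-force checks."""
    cfg = sf.PhantomConfig(
        dims=(32, 32, 32),
        stent_start_mm=4.0,
        stent_end_mm=11.0,
        seed=5,
        fat_mean=-85.0,
        fat_sd=6.0,
    )
    vol, truth = sf.generate_phantom(cfg)
    cl = sf.extract_centerline(truth.lumen_mask, vol.spacing)
    return cfg, vol, truth, cl


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment-convergence checks."""
    return sf.generate_cohort(sf.CohortConfig(n_isr=5000, n_nonisr=5000, seed=11))


def brute_force_fai(volume, centerline, annotation, window=(-190.0, -30.0)):
    """Exhaustive per-voxel FAI oracle: project every voxel center onto the
    finely resampled centerline over ALL segments and apply the geometric
    and HU-window predicates directly."""
    fine = centerline.resample(0.05)
    P, A = fine.points, fine.arc
    seg = P[1:] - P[:-1]
    seglen2 = np.einsum("ij,ij->i", seg, seg)
    R = annotation.diameter_mm / 2.0
    D = annotation.diameter_mm
    lo, hi = annotation.start_mm, annotation.end_mm
    centers = volume.voxel_centers().reshape(-1, 3)
    vals = volume.data.reshape(-1)
    n_shell = n_win = 0
    total = 0.0
    for i, c in enumerate(centers):
        rel = c - P[:-1]
        t = np.clip(np.einsum("ij,ij->i", rel, seg) / seglen2, 0.0, 1.0)
        proj = P[:-1] + t[:, None] * seg
        d = np.linalg.norm(c - proj, axis=1)
        j = int(np.argmin(d))
        r = d[j]
        s = A[j] + t[j] * np.sqrt(seglen2[j])
        if lo <= s <= hi and R < r <= R + D:
            n_shell += 1
            if window[0] <= vals[i] <= window[1]:
                n_win += 1
                total += vals[i]
    return total / n_win, n_shell, n_win
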