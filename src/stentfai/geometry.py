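"""Vessel geometry: centerlines, perpendicular cross-sections, lumen profiling.

Coordinate conventions used throughout the package:

* world coordinates are in millimetres;
* voxel indices are 0-based and follow the (x, y, z) axis order of the
  stored array;
* the *voxel-center* convention places the center of voxel ``(i, j, k)``
  at ``origin + index * spacing``;
* centerline arc length is measured from the ostium (the endpoint nearest
  the volume boundary), in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize


class GeometryError(ValueError):
    """Invalid geometric input (degenerate mask, out-of-range arc position...)."""


class ProximalExclusionError(GeometryError):
    """Stent too close to the ostium for a proximal reference window.

    Mirrors the clinical exclusion of stents positioned within 10 mm of the
    vessel origin, where no normal proximal reference segment exists.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelGrid:
    """A 3D attenuation volume (HU) with isotropic or anisotropic spacing."""

    data: np.ndarray  # (nx, ny, nz) float, Hounsfield units
    spacing: np.ndarray  # (3,) mm per voxel
    origin: np.ndarray = None  # (3,) world mm of voxel (0,0,0) center

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise GeometryError("voxel spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume contains non-finite HU values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``dims + (3,)``."""
        axes = [
            self.origin[a] + np.arange(self.data.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


@dataclass
class Centerline:
    """Ordered vessel centerline with arc length and unit tangents.

    Arc length 0 is the ostium (first point).
    """

    points: np.ndarray  # (n, 3) world mm
    arc: np.ndarray  # (n,) cumulative arc length, arc[0] == 0
    tangents: np.ndarray  # (n, 3) unit tangents
    _frames: np.ndarray = field(default=None, repr=False, compare=False)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Centerline":
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise GeometryError("centerline needs at least two points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 1e-12])
        pts = pts[keep]
        if len(pts) < 2:
            raise GeometryError("centerline points are all coincident")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # central differences, one-sided at the ends
        tan = np.gradient(pts, arc, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return cls(points=pts, arc=arc, tangents=tan)

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def _check_s(self, s: float) -> None:
        if not (0.0 - 1e-9 <= s <= self.length + 1e-9):
            raise GeometryError(
                f"arc position {s} outside centerline range [0, {self.length:.3f}]"
            )

    def point_at(self, s: float) -> np.ndarray:
        self._check_s(s)
        return np.array(
            [np.interp(s, self.arc, self.points[:, a]) for a in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        self._check_s(s)
        t = np.array(
            [np.interp(s, self.arc, self.tangents[:, a]) for a in range(3)]
        )
        return t / np.linalg.norm(t)

    def resample(self, step: float) -> "Centerline":
        if step <= 0:
            raise GeometryError("resample step must be positive")
        n = max(int(np.floor(self.length / step)) + 1, 2)
        svals = np.linspace(0.0, self.length, n)
        pts = np.column_stack(
            [np.interp(svals, self.arc, self.points[:, a]) for a in range(3)]
        )
        return Centerline.from_points(pts)

    # -- parallel-transport frames -----------------------------------------
    def frames(self) -> np.ndarray:
        """In-plane orthonormal frames (n, 2, 3) transported along the curve.

        The initial in-plane axis is the canonical axis (smallest index) least
        parallel to the first tangent, orthogonalised; subsequent frames are
        rotated by the minimal rotation mapping tangent i to tangent i+1,
        which avoids in-plane twist.
        """
        if self._frames is not None:
            return self._frames
        tan = self.tangents
        # pick canonical seed axis: smallest-index axis with |dot| minimal ties
        dots = np.abs(tan[0])
        seed = np.eye(3)[int(np.argmin(dots))]
        u = seed - np.dot(seed, tan[0]) * tan[0]
        u /= np.linalg.norm(u)
        frames = np.empty((len(tan), 2, 3))
        for i in range(len(tan)):
            if i > 0:
                u = _rotate_between(tan[i - 1], tan[i]) @ u
                u -= np.dot(u, tan[i]) * tan[i]
                u /= np.linalg.norm(u)
            v = np.cross(tan[i], u)
            frames[i, 0] = u
            frames[i, 1] = v
        self._frames = frames
        return frames

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        self._check_s(s)
        frames = self.frames()
        i = int(np.searchsorted(self.arc, s, side="right") - 1)
        i = min(max(i, 0), len(self.arc) - 1)
        t = self.tangent_at(s)
        u = frames[i, 0]
        u = u - np.dot(u, t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return u, v

    def nearest(self, pts: np.ndarray, fine_step: float = 0.05):
        """Project points orthogonally onto the polyline.

        Returns ``(s, r)``: arc position of the nearest curve point and the
        radial distance, both in mm. Uses a finely resampled polyline with a
        KD-tree prefilter, then exact projection onto adjacent segments.
        """
        fine = self if (np.diff(self.arc).max() <= fine_step) else self.resample(fine_step)
        return _project_to_polyline(fine.points, fine.arc, np.asarray(pts, float))


def _rotate_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a to unit vector b."""
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    if np.linalg.norm(c) < 1e-14:
        return np.eye(3) if d > 0 else -np.eye(3)
    k = np.array(
        [[0, -c[2], c[1]], [c[2], 0, -c[0]], [-c[1], c[0], 0]]
    )
    return np.eye(3) + k + k @ k / (1.0 + d)


def _project_to_polyline(pts_fine, arc_fine, query):
    """Exact orthogonal projection of query points onto a fine polyline."""
    query = query.reshape(-1, 3)
    tree = cKDTree(pts_fine)
    _, idx = tree.query(query, k=1)
    n = len(pts_fine)
    best_d = np.full(len(query), np.inf)
    best_s = np.zeros(len(query))
    # segments adjacent to the nearest vertex
    for lo in (idx - 1, idx):
        a = np.clip(lo, 0, n - 2)
        p0 = pts_fine[a]
        p1 = pts_fine[a + 1]
        d01 = p1 - p0
        ll = np.einsum("ij,ij->i", d01, d01)
        t = np.einsum("ij,ij->i", query - p0, d01) / np.maximum(ll, 1e-30)
        t = np.clip(t, 0.0, 1.0)
        proj = p0 + t[:, None] * d01
        d = np.linalg.norm(query - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_s[better] = arc_fine[a[better]] + t[better] * np.sqrt(ll[better])
    return best_s, best_d


@dataclass
class StentAnnotation:
    """Location and dimensions of an implanted stent on the centerline."""

    vessel: str  # LAD | LCx | RCA
    segment: str  # proximal | middle | distal
    start_mm: float  # arc length of stent start
    end_mm: float  # arc length of stent end
    diameter_mm: float
    stent_class: str = "DES"  # DES | BMS
    length_mm: float = None

    def __post_init__(self) -> None:
        if self.vessel not in {"LAD", "LCx", "RCA"}:
            raise GeometryError(f"unknown vessel {self.vessel!r}")
        if self.segment not in {"proximal", "middle", "distal"}:
            raise GeometryError(f"unknown segment {self.segment!r}")
        if self.stent_class not in {"DES", "BMS"}:
            raise GeometryError(f"unknown stent class {self.stent_class!r}")
        if not self.end_mm > self.start_mm:
            raise GeometryError("stent end must exceed start")
        if self.diameter_mm <= 0:
            raise GeometryError("stent diameter must be positive")
        if self.length_mm is None:
            self.length_mm = self.end_mm - self.start_mm
        if abs(self.length_mm - (self.end_mm - self.start_mm)) > 1e-6:
            raise GeometryError("stent length inconsistent with extent")


@dataclass
class LumenProfile:
    """Lumen diameters along the stented segment and the restenosis call."""

    positions_mm: np.ndarray
    diameters_mm: np.ndarray
    reference_diameter_mm: float
    minimal_diameter_mm: float
    degree_pct: float
    isr: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


_NEIGHBOR_OFFSETS = [
    np.array(o) - 1 for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)
]


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray | None:
    """Voxel indices of the unique longest endpoint-to-endpoint skeleton path.

    Returns None when the skeleton is empty or too small to define a path;
    raises when it branches without a unique longest path.
    """
    coords = np.argwhere(skel)
    if len(coords) < 2:
        return None
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _NEIGHBOR_OFFSETS:
            j = index.get(tuple(c + off))
            if j is not None:
                adj[i].append(j)
    endpoints = [i for i, nb in enumerate(adj) if len(nb) == 1]
    if len(endpoints) < 2:
        return None

    def bfs(src):
        dist = np.full(len(coords), -1, dtype=int)
        parent = np.full(len(coords), -1, dtype=int)
        dist[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    best = None
    n_best = 0
    for src in endpoints:
        dist, parent = bfs(src)
        if (dist < 0).any():
            return None  # fragmented skeleton
        for dst in endpoints:
            if dst <= src:
                continue
            if best is None or dist[dst] > best[0]:
                best = (dist[dst], src, dst, parent)
                n_best = 1
            elif dist[dst] == best[0]:
                n_best += 1
    if n_best > 1:
        raise GeometryError("branching skeleton with no unique longest path")
    _, src, dst, parent = best
    path = [dst]
    while path[-1] != src:
        path.append(int(parent[path[-1]]))
    return coords[path[::-1]]


class _MaskGraph:
    """26-connectivity voxel graph over a mask, with geodesic utilities."""

    def __init__(self, mask: np.ndarray, spacing: np.ndarray):
        from scipy.sparse import coo_matrix

        self.mask = mask
        self.spacing = spacing
        self.coords = np.argwhere(mask)
        n = len(self.coords)
        index = np.full(mask.shape, -1, dtype=np.int64)
        index[tuple(self.coords.T)] = np.arange(n)
        rows, cols, lens = [], [], []
        half = [o for o in _NEIGHBOR_OFFSETS if tuple(o) > (0, 0, 0)]
        for off in half:
            dst = self.coords + off
            ok = np.all((dst >= 0) & (dst < mask.shape), axis=1)
            j = np.full(n, -1, dtype=np.int64)
            j[ok] = index[tuple(dst[ok].T)]
            keep = j >= 0
            rows.append(np.arange(n)[keep])
            cols.append(j[keep])
            lens.append(np.full(keep.sum(), np.linalg.norm(off * spacing)))
        self.rows = np.concatenate(rows)
        self.cols = np.concatenate(cols)
        self.lens = np.concatenate(lens)
        self._coo = coo_matrix
        self.g_len = coo_matrix((self.lens, (self.rows, self.cols)), shape=(n, n)).tocsr()

    def farthest_pair(self) -> tuple[int, int, float]:
        """Double-sweep approximation of the geodesic diameter."""
        from scipy.sparse.csgraph import dijkstra as cs_dijkstra

        d0 = cs_dijkstra(self.g_len, directed=False, indices=0)
        if not np.all(np.isfinite(d0)):
            raise GeometryError("mask is not geodesically connected")
        a = int(np.argmax(d0))
        da = cs_dijkstra(self.g_len, directed=False, indices=a)
        b = int(np.argmax(da))
        return a, b, float(da[b])

    def medial_path(self, a: int, b: int) -> np.ndarray:
        """Minimum-cost a->b path penalising distance from the EDT ridge."""
        from scipy.sparse.csgraph import dijkstra as cs_dijkstra

        edt = ndimage.distance_transform_edt(self.mask, sampling=self.spacing)[
            tuple(self.coords.T)
        ]
        eps = 0.5 * float(self.spacing.min())
        w = ((edt.max() + eps) / (edt + eps)) ** 2
        cost = self.lens * 0.5 * (w[self.rows] + w[self.cols])
        n = len(self.coords)
        g_med = self._coo((cost, (self.rows, self.cols)), shape=(n, n)).tocsr()
        _, pred = cs_dijkstra(g_med, directed=False, indices=a, return_predecessors=True)
        path = [b]
        while path[-1] != a:
            p = int(pred[path[-1]])
            if p < 0:
                raise GeometryError("mask is not geodesically connected")
            path.append(p)
        return self.coords[path[::-1]]


def _recentre_path(
    pts: np.ndarray, mask_centers: np.ndarray, spacing: np.ndarray, iters: int = 2
) -> np.ndarray:
    """Snap path points to the centroid of their perpendicular lumen slab."""
    half_slab = 0.5 * float(spacing.min())
    pts = pts.copy()
    k = min(5, max(len(pts) // 4, 1))
    for _ in range(iters):
        tan = np.gradient(pts, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        # end tangents are unreliable (thinning corners): borrow interior ones
        tan[:k] = tan[k]
        tan[-k:] = tan[-(k + 1)]
        for i in range(len(pts)):
            rel = mask_centers - pts[i]
            along = rel @ tan[i]
            radial2 = np.einsum("ij,ij->i", rel, rel) - along**2
            sel = (np.abs(along) <= half_slab) & (radial2 <= 25.0)
            if sel.sum() < 3:
                continue
            shift = rel[sel].mean(axis=0)
            shift -= (shift @ tan[i]) * tan[i]  # move only within the plane
            pts[i] = pts[i] + shift
    return pts


def extract_centerline(
    mask: np.ndarray,
    spacing,
    origin=None,
    smooth_window: int = 5,
    step: float = 0.5,
) -> Centerline:
    """Extract a vessel centerline from a binary lumen mask.

    Skeletonizes the mask and takes the unique longest path between skeleton
    endpoints; when thinning yields no usable single path (it can annihilate
    tubes whose cross-section has no central voxel), a medial-ridge path
    (distance-transform-weighted shortest path between the geodesically
    farthest voxels) is used instead. The path is recentred on perpendicular
    cross-section centroids, smoothed with a moving average and resampled at
    a fixed arc-length step. The endpoint nearest the volume boundary is the
    ostium (arc length 0).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float).reshape(3)
    if mask.ndim != 3:
        raise GeometryError("lumen mask must be 3D")
    if not mask.any():
        raise GeometryError("lumen mask is empty")
    labeled, ncomp = cc_label(mask, connectivity=1, return_num=True)
    if ncomp != 1:
        raise GeometryError(f"lumen mask has {ncomp} connected components, expected 1")
    if mask.sum() < 4:
        raise GeometryError("lumen mask too small to define a centerline")

    graph = _MaskGraph(mask, spacing)
    a, b, geo_diam = graph.farthest_pair()
    vox = _skeleton_longest_path(skeletonize(mask))
    if vox is not None:
        # reject partial skeletons (3D thinning can annihilate wide sections)
        path_len = np.linalg.norm(np.diff(vox * spacing, axis=0), axis=1).sum()
        if path_len < 0.8 * geo_diam:
            vox = None
    if vox is None:
        vox = graph.medial_path(a, b)
    vox = vox.astype(float)

    if smooth_window > 1:
        vox = ndimage.uniform_filter1d(vox, size=smooth_window, axis=0, mode="nearest")

    pts = origin + vox * spacing
    mask_centers = origin + np.argwhere(mask) * spacing
    pts = _recentre_path(pts, mask_centers, spacing)
    if smooth_window > 1:
        pts = ndimage.uniform_filter1d(pts, size=smooth_window, axis=0, mode="nearest")

    # orient: ostium = endpoint nearest the volume boundary (world mm)
    dims = np.asarray(mask.shape)

    def boundary_dist(p):
        idx = (p - origin) / spacing
        return float(np.min(np.minimum(idx, dims - 1 - idx) * spacing))

    if boundary_dist(pts[-1]) < boundary_dist(pts[0]):
        pts = pts[::-1]

    return Centerline.from_points(pts).resample(step)


def resample_cross_section(
    volume: VoxelGrid,
    centerline: Centerline,
    s: float,
    half_width: float,
    pixel: float,
) -> np.ndarray:
    """Resample the attenuation plane orthogonal to the centerline at arc s.

    Returns a square 2D slab of side ``2*floor(half_width/pixel)+1`` pixels,
    centered on the centerline point; samples outside the volume are NaN.
    """
    centerline._check_s(s)
    if pixel <= 0:
        raise GeometryError("pixel size must be positive")
    p = centerline.point_at(s)
    u, v = centerline.frame_at(s)
    m = int(np.floor(half_width / pixel + 1e-9))
    offs = np.arange(-m, m + 1) * pixel
    aa, bb = np.meshgrid(offs, offs, indexing="ij")
    world = p + aa[..., None] * u + bb[..., None] * v
    ijk = volume.world_to_voxel(world.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(
        volume.data, ijk, order=1, mode="constant", cval=np.nan
    )
    return vals.reshape(aa.shape)


def measure_lumen_diameter(
    slab: np.ndarray,
    pixel: float,
    contrast_threshold: float = 180.0,
    upper_threshold: float = 600.0,
) -> float:
    """Equivalent-circle lumen diameter from a thresholded cross-section.

    Keeps the connected component of contrast-range pixels
    (``contrast_threshold <= HU < upper_threshold``; the upper bound
    excludes metallic stent struts) containing the slab center and returns
    ``2*sqrt(area/pi)``; 0.0 if the center pixel is outside the contrast
    range (occluded lumen).
    """
    slab = np.asarray(slab, dtype=float)
    filled = np.where(np.isnan(slab), -np.inf, slab)
    binary = (filled >= contrast_threshold) & (filled < upper_threshold)
    ci = tuple(n // 2 for n in slab.shape)
    if not binary[ci]:
        return 0.0
    lab = cc_label(binary, connectivity=1)
    area = float(np.sum(lab == lab[ci])) * pixel * pixel
    return 2.0 * np.sqrt(area / np.pi)


def degree_of_isr(d_prox: float, d_min: float) -> float:
    """Percent diameter stenosis relative to the normal proximal lumen.

    ``100 * (d_prox - d_min) / d_prox``; a minimal diameter exceeding the
    reference is clipped to 0 % (no restenosis).
    """
    if d_prox <= 0:
        raise GeometryError("proximal reference diameter must be positive")
    if d_min < 0:
        raise GeometryError("minimal diameter must be non-negative")
    if d_min >= d_prox:
        return 0.0
    return float(min(100.0 * (d_prox - d_min) / d_prox, 100.0))


def compute_lumen_profile(
    volume: VoxelGrid,
    centerline: Centerline,
    annotation: StentAnnotation,
    step: float = 0.5,
    contrast_threshold: float = 180.0,
    isr_threshold_pct: float = 50.0,
    edge_margin_mm: float = 5.0,
    reference_window_mm: tuple[float, float] = (10.0, 5.0),
    pixel: float = 0.2,
    half_width: float = None,
) -> LumenProfile:
    """Profile lumen diameters over the stent and its edge segments.

    Restenosis is assessed over the stent plus ``edge_margin_mm`` adjacent
    segments on each side; the normal proximal reference diameter is the
    median over the window ``[start - ref_far, start - ref_near]`` mm.
    A stent whose reference window would extend proximal to the ostium is
    rejected (proximal-exclusion), mirroring the clinical exclusion rule.
    """
    ref_far, ref_near = reference_window_mm
    if annotation.start_mm - ref_far < -1e-9:
        raise ProximalExclusionError(
            "proximal-exclusion: stent within "
            f"{ref_far:g} mm of the ostium (start {annotation.start_mm:g} mm)"
        )
    if annotation.end_mm + edge_margin_mm > centerline.length + 1e-9:
        raise GeometryError("stent edge segment extends beyond the centerline")
    if half_width is None:
        half_width = annotation.diameter_mm

    def diam(s):
        slab = resample_cross_section(volume, centerline, s, half_width, pixel)
        return measure_lumen_diameter(slab, pixel, contrast_threshold)

    ref_pos = np.arange(
        annotation.start_mm - ref_far, annotation.start_mm - ref_near + 1e-9, step
    )
    d_ref = float(np.median([diam(s) for s in ref_pos]))
    if d_ref <= 0:
        raise GeometryError("no measurable proximal reference lumen")

    pos = np.arange(
        annotation.start_mm - edge_margin_mm,
        annotation.end_mm + edge_margin_mm + 1e-9,
        step,
    )
    diams = np.array([diam(s) for s in pos])
    d_min = float(diams.min())
    deg = degree_of_isr(d_ref, min(d_min, d_ref))
    return LumenProfile(
        positions_mm=pos,
        diameters_mm=diams,
        reference_diameter_mm=d_ref,
        minimal_diameter_mm=d_min,
        degree_pct=deg,
        isr=bool(deg >= isr_threshold_pct),
    )
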