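"""Automated restoration of the pre-pathological vessel wall.

Wall vertices inside the detected dilation are pulled radially toward the
centerline until their radius matches an interpolated healthy target, then
relaxed by constrained Laplacian smoothing (the radial component of each
smoothing step is re-projected onto the target radius, so smoothing removes
angular/axial roughness without shrinking the tube).  Vertices outside the
region plus a fixed two-ring collar are left bit-identical.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .geometry import Centerline, SurfaceMesh
from .morphology import CrossSectionProfile, DilationRegion

__all__ = ["TargetRadiusProfile", "target_radius_profile", "remove_dilation"]

DEFAULT_LAMBDA = 0.5
DEFAULT_ITERATIONS = 20


@dataclasses.dataclass
class TargetRadiusProfile:
    """Healthy-lumen radius as a function of arc length."""

    s_start: float
    s_end: float
    _inside: PchipInterpolator
    _measured_s: np.ndarray
    _measured_r: np.ndarray
    blend_margin: float = 0.0

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        inside = (s >= self.s_start) & (s <= self.s_end)
        r = np.interp(s, self._measured_s, self._measured_r)
        if np.any(inside):
            r = np.where(inside, self._inside(np.clip(s, self.s_start, self.s_end)), r)
        return r if r.ndim else float(r)


def target_radius_profile(
    profile: CrossSectionProfile, region: DilationRegion, blend_margin: float = 1.0
) -> TargetRadiusProfile:
    """Monotone interpolation of the healthy radius across the dilation.

    Inside the region the target is a monotone cubic between the measured
    equivalent radii at the proximal and distal region boundaries; outside it
    equals the measured radius.
    """
    s = profile.s_values
    r = profile.d_eq_values / 2.0
    if region.s_start <= s[0] or region.s_end >= s[-1]:
        raise ValueError("region must be strictly inside the profile")
    r_prox = float(np.interp(region.s_start, s, r))
    r_dist = float(np.interp(region.s_end, s, r))
    interp = PchipInterpolator(
        [region.s_start, region.s_end], [r_prox, r_dist]
    )
    return TargetRadiusProfile(
        s_start=region.s_start,
        s_end=region.s_end,
        _inside=interp,
        _measured_s=s,
        _measured_r=r,
        blend_margin=blend_margin,
    )


def _two_ring(mesh: SurfaceMesh, seed: np.ndarray) -> np.ndarray:
    """Vertex set grown by two edge rings from ``seed`` (boolean mask)."""
    nbrs = mesh.vertex_neighbors()
    grown = seed.copy()
    for _ in range(2):
        new = grown.copy()
        for v in np.flatnonzero(grown):
            new[nbrs[v]] = True
        grown = new
    return grown


def _self_intersects(mesh: SurfaceMesh, tri_subset: np.ndarray) -> bool:
    """Check the triangle subset for pairwise intersections (non-adjacent pairs).

    Candidate pairs come from a centroid KD-tree radius query; each candidate
    pair is tested by segment-triangle intersection of all six edges.
    """
    tris = mesh.triangles[tri_subset]
    v = mesh.vertices
    corners = v[tris]  # (m, 3, 3)
    centroids = corners.mean(axis=1)
    circum = np.linalg.norm(corners - centroids[:, None, :], axis=2).max(axis=1)
    rad = 2.0 * float(circum.max()) if len(circum) else 0.0
    if rad == 0.0:
        return False
    tree = cKDTree(centroids)
    pairs = np.array(list(tree.query_pairs(rad)), dtype=np.int64)
    if pairs.size == 0:
        return False
    a, b = pairs[:, 0], pairs[:, 1]
    # exclude adjacent pairs (shared vertex)
    shared = np.zeros(len(pairs), dtype=bool)
    for i in range(3):
        for j in range(3):
            shared |= tris[a, i] == tris[b, j]
    pairs = pairs[~shared]
    for a, b in pairs:
        if _tri_tri_overlap(corners[a], corners[b]):
            return True
    return False


def _seg_tri_hit(p0: np.ndarray, p1: np.ndarray, tri: np.ndarray) -> bool:
    """Segment-triangle intersection test (strict interior hit)."""
    d = p1 - p0
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < 1e-14:
        return False
    f = 1.0 / det
    s = p0 - tri[0]
    u = f * (s @ h)
    if u < 1e-9 or u > 1 - 1e-9:
        return False
    q = np.cross(s, e1)
    w = f * (d @ q)
    if w < 1e-9 or u + w > 1 - 1e-9:
        return False
    t = f * (e2 @ q)
    return 1e-9 < t < 1 - 1e-9


def _tri_tri_overlap(t1: np.ndarray, t2: np.ndarray) -> bool:
    for i in range(3):
        if _seg_tri_hit(t1[i], t1[(i + 1) % 3], t2):
            return True
        if _seg_tri_hit(t2[i], t2[(i + 1) % 3], t1):
            return True
    return False


def remove_dilation(
    mesh: SurfaceMesh,
    cl: Centerline,
    region: DilationRegion,
    target: TargetRadiusProfile,
    lam: float = DEFAULT_LAMBDA,
    iterations: int = DEFAULT_ITERATIONS,
    check_intersections: bool = True,
) -> SurfaceMesh:
    """Return a new mesh with the dilation shrunk to the target radius.

    The vertex "radius" is the distance to its orthogonal foot point on the
    centerline; equidistant feet resolve to the smaller-s station.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    out = mesh.copy()
    feet, s_v, r_v = cl.foot_points(out.vertices)
    in_region = (s_v > region.s_start) & (s_v < region.s_end)
    if not np.any(in_region):
        return out

    radial = out.vertices - feet
    with np.errstate(invalid="ignore"):
        radial_unit = radial / np.where(r_v[:, None] > 0, r_v[:, None], 1.0)
    r_tgt = np.asarray(target(s_v), dtype=float)

    # radial remap: pull region vertices onto the target radius
    verts = out.vertices.copy()
    idx = np.flatnonzero(in_region)
    verts[idx] = feet[idx] + radial_unit[idx] * r_tgt[idx, None]

    # constrained Laplacian relaxation; two-ring collar stays fixed
    collar = _two_ring(out, in_region) & ~in_region
    nbrs = out.vertex_neighbors()
    flat_nb = np.concatenate([nbrs[v] for v in idx]) if len(idx) else np.empty(0, int)
    counts = np.array([len(nbrs[v]) for v in idx])
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    for _ in range(iterations):
        updated = verts.copy()
        sums = np.add.reduceat(verts[flat_nb], offsets, axis=0)
        means = sums / counts[:, None]
        updated[idx] = verts[idx] + lam * (means - verts[idx])
        # re-project the smoothed position to the target radius at its station
        foot_u, s_u, r_u = cl.foot_points(updated[idx])
        good = r_u > 1e-12
        dir_u = np.where(
            good[:, None], (updated[idx] - foot_u), radial_unit[idx] * 1.0
        )
        dir_u /= np.linalg.norm(dir_u, axis=1, keepdims=True)
        r_new = np.asarray(target(np.clip(s_u, region.s_start, region.s_end)))
        verts[idx] = foot_u + dir_u * r_new[:, None]

    out.vertices = verts
    out.check()
    if check_intersections:
        tri_mask = np.any(in_region[out.triangles] | collar[out.triangles], axis=1)
        if _self_intersects(out, np.flatnonzero(tri_mask)):
            raise ValueError(
                "self-intersection after smoothing "
                f"(region s in [{region.s_start:.2f}, {region.s_end:.2f}])"
            )
    return out
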