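"""Shared geometric primitives: surface meshes, centerlines, local frames.

All coordinates are millimeters; areas are mm².  Centerline frames use
parallel transport (rotation-minimizing), not Frenet frames, so they stay
defined on straight segments and never flip between adjacent stations.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "Frame",
    "Centerline",
    "SurfaceMesh",
    "resample_centerline",
    "local_frame",
    "equivalent_diameter",
    "equivalent_radius",
]


@dataclasses.dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal frame attached to a centerline station."""

    origin: np.ndarray
    tangent: np.ndarray
    normal1: np.ndarray
    normal2: np.ndarray

    def validate(self, tol: float = 1e-9) -> None:
        for v in (self.tangent, self.normal1, self.normal2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("frame axis is not unit length")
        if abs(float(self.tangent @ self.normal1)) > tol * 1e3:
            raise ValueError("frame axes not orthogonal")
        if float(np.cross(self.tangent, self.normal1) @ self.normal2) < 0:
            raise ValueError("frame is not right-handed")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def _pick_normal(t: np.ndarray) -> np.ndarray:
    """Any unit vector orthogonal to ``t``."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(ref, t))


class Centerline:
    """Arc-length-parameterized 3D polyline with transported orthonormal frames.

    Parameters
    ----------
    points
        ``(n, 3)`` ordered positions in mm, ``n >= 2``.

    Arc length is recomputed from the points on construction.  Per-point
    tangents are central differences of neighbouring points; ``normal1`` is
    parallel-transported from the first station (projection transport), and
    ``normal2 = tangent x normal1``.
    """

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("centerline needs an (n>=2, 3) point array")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline has duplicate consecutive points")
        self.points = points
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.tangents = self._compute_tangents(points)
        self.normals1, self.normals2 = self._transport_normals(self.tangents)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _compute_tangents(points: np.ndarray) -> np.ndarray:
        d = np.empty_like(points)
        d[0] = points[1] - points[0]
        d[-1] = points[-1] - points[-2]
        d[1:-1] = points[2:] - points[:-2]
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @staticmethod
    def _transport_normals(tangents: np.ndarray):
        n = len(tangents)
        n1 = np.empty_like(tangents)
        n1[0] = _pick_normal(tangents[0])
        for i in range(1, n):
            # project previous normal off the new tangent: rotation-minimizing
            v = n1[i - 1] - (n1[i - 1] @ tangents[i]) * tangents[i]
            norm = np.linalg.norm(v)
            if norm < 1e-12:  # right-angle kink; fall back to arbitrary normal
                v = _pick_normal(tangents[i])
                norm = 1.0
            n1[i] = v / norm
        n2 = np.cross(tangents, n1)
        n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
        return n1, n2

    # -- queries --------------------------------------------------------------

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        self._check_s(s)
        return np.array(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)]
        )

    def frame_at(self, s: float) -> Frame:
        return local_frame(self, s)

    def _check_s(self, s: float) -> None:
        if s < -1e-9 or s > self.total_length + 1e-9:
            raise ValueError(
                f"arc length {s} outside [0, {self.total_length}]"
            )

    def foot_points(self, query: np.ndarray):
        """Orthogonal projection of ``query`` points onto the polyline.

        Returns ``(feet, s, radius)``: closest points on the line, their
        arc-length stations and the query-to-foot distances.  Ties between
        equidistant segments resolve to the smaller station.
        """
        query = np.atleast_2d(np.asarray(query, dtype=float))
        a = self.points[:-1]  # (m, 3) segment starts
        ab = self.points[1:] - a
        ab2 = np.einsum("ij,ij->i", ab, ab)
        # (q, m) parametric foot on each segment, clamped
        t = np.einsum("qmj,mj->qm", query[:, None, :] - a[None], ab) / ab2
        t = np.clip(t, 0.0, 1.0)
        feet = a[None] + t[..., None] * ab[None]
        d2 = np.einsum("qmj->qm", (query[:, None, :] - feet) ** 2)
        best = np.argmin(d2, axis=1)  # argmin takes first == smaller s on ties
        rows = np.arange(len(query))
        foot = feet[rows, best]
        s = self.arc_length[best] + t[rows, best] * np.sqrt(ab2[best])
        radius = np.sqrt(d2[rows, best])
        return foot, s, radius


def resample_centerline(cl: Centerline, spacing: float) -> Centerline:
    """Resample a centerline at uniform arc-length spacing.

    Endpoints are preserved exactly; the actual spacing is the total length
    divided by the nearest integer number of intervals.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = cl.total_length
    if spacing >= total:
        raise ValueError("spacing too coarse")
    n_seg = max(1, round(total / spacing))
    s_new = np.linspace(0.0, total, n_seg + 1)
    pts = np.column_stack(
        [np.interp(s_new, cl.arc_length, cl.points[:, k]) for k in range(3)]
    )
    return Centerline(pts)


def local_frame(cl: Centerline, s: float) -> Frame:
    """Interpolated rotation-minimizing frame at arc length ``s``."""
    cl._check_s(s)
    s = min(max(s, 0.0), cl.total_length)
    i = int(np.searchsorted(cl.arc_length, s, side="right") - 1)
    i = min(i, len(cl.points) - 2)
    w = (s - cl.arc_length[i]) / (cl.arc_length[i + 1] - cl.arc_length[i])
    origin = (1 - w) * cl.points[i] + w * cl.points[i + 1]
    tangent = _unit((1 - w) * cl.tangents[i] + w * cl.tangents[i + 1])
    n1 = (1 - w) * cl.normals1[i] + w * cl.normals1[i + 1]
    n1 = n1 - (n1 @ tangent) * tangent
    n1 = _unit(n1)
    n2 = _unit(np.cross(tangent, n1))
    return Frame(origin=origin, tangent=tangent, normal1=n1, normal2=n2)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area, ``2*sqrt(area/pi)``."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area / math.pi)


def equivalent_radius(area: float) -> float:
    return 0.5 * equivalent_diameter(area)


class SurfaceMesh:
    """Triangulated lumen wall with open inlet/outlet boundary loops.

    ``vertices``: ``(nv, 3)`` float mm; ``triangles``: ``(nt, 3)`` int with
    counter-clockwise winding seen from outside (outward normals).
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        triangles = np.asarray(triangles, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if triangles.ndim != 2 or triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if triangles.size and triangles.max() >= len(vertices):
            raise ValueError("triangle index out of range")
        self.vertices = vertices
        self.triangles = triangles
        self._boundary_loops: list[np.ndarray] | None = None

    # -- derived quantities ---------------------------------------------------

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        if normalized:
            lens = np.linalg.norm(n, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            n = n / lens
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def edge_counts(self):
        e = self.edges()
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def is_manifold(self) -> bool:
        """Every edge shared by at most two triangles."""
        _, counts = self.edge_counts()
        return bool(np.all(counts <= 2))

    def check(self, min_area: float = 1e-12) -> None:
        """Raise on non-manifold edges or degenerate triangles."""
        uniq, counts = self.edge_counts()
        if np.any(counts > 2):
            raise ValueError("non-manifold edge (shared by >2 triangles)")
        if np.any(self.triangle_areas() < min_area):
            raise ValueError("degenerate (zero-area) triangle")

    @property
    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex rings of the open boundaries (inlets/outlets)."""
        if self._boundary_loops is None:
            self._boundary_loops = self._trace_boundary_loops()
        return self._boundary_loops

    def _trace_boundary_loops(self) -> list[np.ndarray]:
        uniq, counts = self.edge_counts()
        bedges = uniq[counts == 1]
        nxt: dict[int, list[int]] = {}
        for a, b in bedges:
            nxt.setdefault(int(a), []).append(int(b))
            nxt.setdefault(int(b), []).append(int(a))
        seen: set[int] = set()
        loops = []
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur, prev = start, -1
            while True:
                cands = [v for v in nxt[cur] if v != prev]
                if not cands:
                    break
                nxt_v = cands[0]
                if nxt_v == start:
                    break
                loop.append(nxt_v)
                seen.add(nxt_v)
                prev, cur = cur, nxt_v
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency: for each vertex, the indices of edge-connected vertices."""
        uniq, _ = self.edge_counts()
        order = np.concatenate([uniq, uniq[:, ::-1]])
        order = order[np.argsort(order[:, 0], kind="stable")]
        starts = np.searchsorted(order[:, 0], np.arange(len(self.vertices)))
        ends = np.searchsorted(order[:, 0], np.arange(len(self.vertices)) + 1)
        return [order[s:e, 1] for s, e in zip(starts, ends)]

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy())
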