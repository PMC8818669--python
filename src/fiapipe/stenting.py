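"""Fast virtual deployment of braided flow-diverter stents.

A braided stent is modelled as ``N_w`` helical wires (half left-handed, half
right-handed) whose total wire length is conserved during deployment.  The
braid kinematics couple the local deployed diameter ``d`` to the local pitch
per turn::

    p(d) = sqrt(l_t**2 - (pi*d)**2),       l_t = pi*D_nom / sin(beta0)

so a stent constrained below its nominal diameter elongates and one opened
to larger diameters shortens.  Deployment marches proximally from the distal
landing position turn by turn, sizing each turn to ``min(lumen d_eq, D_nom)``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Centerline, SurfaceMesh, resample_centerline
from .morphology import CrossSectionProfile, csa_profile

__all__ = [
    "StentSpec",
    "DeployedStent",
    "stent_template",
    "deploy_stent",
    "apposition_map",
    "metal_coverage",
]

DEFAULT_BRAID_ANGLE = 75.0  # deg, to the stent axis
DEFAULT_MALAPPOSITION_THRESHOLD = 0.25  # mm
POINTS_PER_TURN = 72


@dataclasses.dataclass(frozen=True)
class StentSpec:
    """Nominal braided-device parameters."""

    length: float  # L_nom, mm
    diameter: float  # D_nom, mm
    n_wires: int  # N_w, even
    strut_thickness_um: float  # t_s, micrometers
    braid_angle_deg: float = DEFAULT_BRAID_ANGLE  # beta0, to the axis

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")
        if self.n_wires < 2 or self.n_wires % 2:
            raise ValueError("n_wires must be even and >= 2")
        if self.strut_thickness_um <= 0:
            raise ValueError("strut thickness must be positive")
        if not 0 < self.braid_angle_deg < 90:
            raise ValueError("braid angle must be in (0, 90) degrees")

    @property
    def strut_thickness(self) -> float:
        """Strut thickness in mm."""
        return self.strut_thickness_um * 1e-3

    @property
    def nominal_pitch(self) -> float:
        """Axial advance per full turn at nominal diameter, p0 = pi*D/tan(b)."""
        return math.pi * self.diameter / math.tan(math.radians(self.braid_angle_deg))

    @property
    def wire_length_per_turn(self) -> float:
        """Helix length per full turn, l_t = pi*D/sin(b); conserved quantity."""
        return math.pi * self.diameter / math.sin(math.radians(self.braid_angle_deg))

    @property
    def n_turns(self) -> float:
        return self.length / self.nominal_pitch

    @property
    def max_diameter(self) -> float:
        """Over-expansion limit d_max = l_t/pi (pitch would vanish)."""
        return self.wire_length_per_turn / math.pi


def pitch_at_diameter(spec: StentSpec, d: float) -> float:
    """Local pitch per turn at deployed diameter ``d`` (wire-length conserving)."""
    lt = spec.wire_length_per_turn
    arg = lt * lt - (math.pi * d) ** 2
    if arg <= 0:
        raise ValueError("stent cannot appose: over-expansion limit")
    return math.sqrt(arg)


@dataclasses.dataclass
class DeployedStent:
    spec: StentSpec
    wire_paths: list[np.ndarray]  # per-wire (n, 3) polylines, mm
    turn_s: np.ndarray  # arc-length station at the distal end of each turn
    turn_diameter: np.ndarray  # deployed diameter per turn, mm
    turn_pitch: np.ndarray  # axial pitch per turn, mm
    turn_fraction: np.ndarray  # fraction of a full turn (last may be partial)
    deployed_length: float

    @property
    def wire_length(self) -> float:
        """Total polyline wire length, mm."""
        return float(
            sum(np.linalg.norm(np.diff(w, axis=0), axis=1).sum() for w in self.wire_paths)
        )

    def diameter_at(self, s: float) -> float:
        order = np.argsort(self.turn_s)
        return float(np.interp(s, self.turn_s[order], self.turn_diameter[order]))

    @property
    def s_span(self) -> tuple[float, float]:
        lo = float(self.turn_s.min() - self.turn_pitch[np.argmin(self.turn_s)])
        return lo, float(self.turn_s.max())

    def to_dict(self) -> dict:
        return {
            "L_dep_mm": self.deployed_length,
            "d_min_mm": float(self.turn_diameter.min()),
            "d_max_mm": float(self.turn_diameter.max()),
            "n_turns": float(self.turn_fraction.sum()),
            "wire_length_mm": self.wire_length,
        }


def _wire_phases(n_wires: int):
    half = n_wires // 2
    phases = 2.0 * np.pi * np.arange(half) / half
    return [(p, +1) for p in phases] + [(p, -1) for p in phases]


def _build_wires(
    spec: StentSpec,
    turn_fracs: np.ndarray,
    axial_of_u,
    center_of_axial,
    frame_of_axial,
    radius_of_u,
    points_per_turn: int,
) -> list[np.ndarray]:
    """Sample all wires along cumulative turn parameter ``u``.

    ``axial_of_u`` maps turns-elapsed to axial coordinate; ``center_of_axial``
    and ``frame_of_axial`` give the tube center and (n1, n2) plane axes; the
    deployed radius is ``radius_of_u``.
    """
    total_turns = float(turn_fracs.sum())
    n_pts = max(2, int(math.ceil(total_turns * points_per_turn)) + 1)
    u = np.linspace(0.0, total_turns, n_pts)
    z = axial_of_u(u)
    centers = center_of_axial(z)
    n1, n2 = frame_of_axial(z)
    r = radius_of_u(u)
    wires = []
    for phase, hand in _wire_phases(spec.n_wires):
        theta = phase + hand * 2.0 * np.pi * u
        offs = (np.cos(theta) * r)[:, None] * n1 + (np.sin(theta) * r)[:, None] * n2
        wires.append(centers + offs)
    return wires


def stent_template(spec: StentSpec, points_per_turn: int = POINTS_PER_TURN) -> DeployedStent:
    """Nominal straight configuration: helical wires on a D_nom cylinder."""
    n_turns = spec.n_turns
    n_full = int(math.floor(n_turns + 1e-12))
    fracs = [1.0] * n_full
    if n_turns - n_full > 1e-9:
        fracs.append(n_turns - n_full)
    turn_fracs = np.array(fracs)
    p0 = spec.nominal_pitch
    rad = spec.diameter / 2.0

    ez = np.array([0.0, 0.0, 1.0])
    wires = _build_wires(
        spec,
        turn_fracs,
        axial_of_u=lambda u: u * p0,
        center_of_axial=lambda z: np.outer(z, ez),
        frame_of_axial=lambda z: (
            np.tile([1.0, 0.0, 0.0], (len(z), 1)),
            np.tile([0.0, 1.0, 0.0], (len(z), 1)),
        ),
        radius_of_u=lambda u: np.full_like(u, rad),
        points_per_turn=points_per_turn,
    )
    ends = np.cumsum(turn_fracs * p0)
    return DeployedStent(
        spec=spec,
        wire_paths=wires,
        turn_s=ends,
        turn_diameter=np.full(len(turn_fracs), spec.diameter),
        turn_pitch=np.full(len(turn_fracs), p0),
        turn_fraction=turn_fracs,
        deployed_length=float(ends[-1]),
    )


def deploy_stent(
    spec: StentSpec,
    mesh: SurfaceMesh,
    cl: Centerline,
    s_distal: float,
    profile: CrossSectionProfile | None = None,
    points_per_turn: int = POINTS_PER_TURN,
    profile_spacing: float = 0.5,
    profile_n_rays: int = 90,
) -> DeployedStent:
    """Deploy the stent in a lumen, marching proximally from ``s_distal``.

    Each turn is sized to ``d = min(lumen d_eq, D_nom)`` at its distal end and
    advances ``p(d)`` proximally; the template's total turn count is placed,
    conserving total wire length.
    """
    if not 0 < s_distal <= cl.total_length:
        raise ValueError("s_distal outside the vessel")
    if profile is None:
        profile = csa_profile(mesh, cl, spacing=profile_spacing, n_rays=profile_n_rays)
    s_prof = profile.s_values
    d_prof = profile.d_eq_values

    n_turns = spec.n_turns
    n_full = int(math.floor(n_turns + 1e-12))
    fracs = [1.0] * n_full
    if n_turns - n_full > 1e-9:
        fracs.append(n_turns - n_full)

    turn_s, turn_d, turn_p, turn_f = [], [], [], []
    s = float(s_distal)
    for frac in fracs:
        d = min(float(np.interp(s, s_prof, d_prof)), spec.diameter)
        p = pitch_at_diameter(spec, d)
        turn_s.append(s)
        turn_d.append(d)
        turn_p.append(p)
        turn_f.append(frac)
        s -= p * frac
        if s < -1e-9:
            raise ValueError("landing zone shorter than achievable deployed length")
    turn_s = np.array(turn_s)
    turn_d = np.array(turn_d)
    turn_p = np.array(turn_p)
    turn_f = np.array(turn_f)
    l_dep = float(np.sum(turn_p * turn_f))

    # cumulative turns -> arc-length station (piecewise linear, distal to proximal)
    u_edges = np.concatenate([[0.0], np.cumsum(turn_f)])
    s_edges = np.concatenate([[s_distal], s_distal - np.cumsum(turn_p * turn_f)])
    d_edges = np.concatenate([[turn_d[0]], turn_d])

    fine = resample_centerline(cl, min(0.1, turn_p.min() / 8.0))

    def axial_of_u(u):
        return np.interp(u, u_edges, s_edges)

    def center_of_axial(s_arr):
        return np.column_stack(
            [np.interp(s_arr, fine.arc_length, fine.points[:, k]) for k in range(3)]
        )

    def frame_of_axial(s_arr):
        i = np.clip(
            np.searchsorted(fine.arc_length, s_arr) , 0, len(fine.points) - 1
        )
        return fine.normals1[i], fine.normals2[i]

    def radius_of_u(u):
        return np.interp(u, u_edges, d_edges) / 2.0

    wires = _build_wires(
        spec, turn_f, axial_of_u, center_of_axial, frame_of_axial, radius_of_u,
        points_per_turn,
    )
    return DeployedStent(
        spec=spec,
        wire_paths=wires,
        turn_s=turn_s,
        turn_diameter=turn_d,
        turn_pitch=turn_p,
        turn_fraction=turn_f,
        deployed_length=l_dep,
    )


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from each point to one triangle (vectorized over points)."""
    a, b, c = tri
    ab, ac = b - a, c - a
    ap = points - a
    d1 = ap @ ab
    d2 = ap @ ac
    n = np.cross(ab, ac)
    nn = n @ n
    if nn < 1e-30:
        return np.linalg.norm(ap, axis=1)
    # barycentric of the plane projection
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    den = d00 * d11 - d01 * d01
    v = (d11 * d1 - d01 * d2) / den
    w = (d00 * d2 - d01 * d1) / den
    u = 1.0 - v - w
    inside = (u >= 0) & (v >= 0) & (w >= 0)
    proj = a + np.outer(v, ab) + np.outer(w, ac)
    d_plane = np.linalg.norm(points - proj, axis=1)

    def seg_dist(p0, seg):
        t = np.clip((points - p0) @ seg / (seg @ seg), 0.0, 1.0)
        return np.linalg.norm(points - (p0 + np.outer(t, seg)), axis=1)

    d_edges = np.minimum.reduce(
        [seg_dist(a, ab), seg_dist(a, ac), seg_dist(b, c - b)]
    )
    return np.where(inside, d_plane, d_edges)


def surface_distance(points: np.ndarray, mesh: SurfaceMesh, k: int = 12) -> np.ndarray:
    """Distance from points to the mesh surface via KD-tree candidate triangles."""
    corners = mesh.vertices[mesh.triangles]
    centroids = corners.mean(axis=1)
    tree = cKDTree(centroids)
    k = min(k, len(centroids))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    # group all (point, candidate-triangle) pairs by triangle for vector math
    pt_idx = np.repeat(np.arange(len(points)), cand.shape[1])
    tri_idx = cand.ravel()
    order = np.argsort(tri_idx, kind="stable")
    pt_idx, tri_idx = pt_idx[order], tri_idx[order]
    dist = np.full(len(points), np.inf)
    starts = np.flatnonzero(np.diff(tri_idx, prepend=-1))
    bounds = np.append(starts, len(tri_idx))
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        rows = pt_idx[s0:s1]
        d = _point_triangle_distance(points[rows], corners[tri_idx[s0]])
        np.minimum.at(dist, rows, d)
    return dist


def apposition_map(
    stent: DeployedStent,
    mesh: SurfaceMesh,
    threshold: float = DEFAULT_MALAPPOSITION_THRESHOLD,
) -> dict:
    """Wire-to-wall gaps and malapposition flags.

    gap = distance(wire point, wall) - t_s/2, clamped at zero (contact or
    strut/wall interpenetration counts as fully apposed); flagged where
    gap > threshold.
    """
    pts = np.concatenate(stent.wire_paths)
    gaps = surface_distance(pts, mesh) - stent.spec.strut_thickness / 2.0
    gaps = np.maximum(gaps, 0.0)
    flags = gaps > threshold
    return {
        "gaps": gaps,
        "malapposed": flags,
        "max_gap_mm": float(gaps.max()),
        "malapposed_fraction": float(flags.mean()),
        "threshold_mm": threshold,
    }


def metal_coverage(stent: DeployedStent, s_start: float, s_end: float) -> float:
    """Strut footprint fraction of the lateral tube surface over [s_start, s_end].

    Per turn: footprint = N_w * l_t * t_s minus the double-counted crossing
    overlaps; opposite-handed wires cross N_w^2/2 times per turn, each overlap
    a parallelogram of area t_s^2 / sin(2*beta_local) with the local braid
    angle beta_local = asin(pi*d / l_t).
    """
    if s_start >= s_end:
        raise ValueError("require s_start < s_end")
    ts = stent.spec.strut_thickness
    lt = stent.spec.wire_length_per_turn
    nw = stent.spec.n_wires
    covered = wall = 0.0
    any_overlap = False
    for s_hi, d, p, f in zip(
        stent.turn_s, stent.turn_diameter, stent.turn_pitch, stent.turn_fraction
    ):
        lo, hi = s_hi - p * f, s_hi
        ov = max(0.0, min(hi, s_end) - max(lo, s_start))
        if ov <= 0:
            continue
        any_overlap = True
        w = ov / p  # fraction of the turn inside the segment
        sin_b = math.pi * d / lt
        sin_2b = 2.0 * sin_b * math.sqrt(max(0.0, 1.0 - sin_b * sin_b))
        n_cross = nw * nw / 2.0
        footprint = nw * lt * ts - n_cross * ts * ts / max(sin_2b, 1e-9)
        covered += w * footprint
        wall += w * math.pi * d * p
    if not any_overlap:
        raise ValueError("segment outside stent")
    return float(min(1.0, max(0.0, covered / wall)))
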