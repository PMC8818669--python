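"""Cross-sectional-area profiling and fusiform-dilation detection.

The lumen cross-section at a centerline station is sampled by casting rays
from the station origin, uniformly spaced in angle within the plane
perpendicular to the local tangent.  The first outward-facing surface hit of
each ray bounds the lumen; the enclosed area is the fan-polygon area of the
hit points about the origin.

A dilation is classified as fusiform when its equivalent diameter exceeds
``huber_ratio`` (default 1.5) times the nominal vessel diameter.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .geometry import Centerline, Frame, SurfaceMesh, equivalent_diameter, resample_centerline

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSection",
    "CrossSectionProfile",
    "DilationRegion",
    "MorphologyReport",
    "cross_section_area",
    "csa_profile",
    "nominal_diameter",
    "detect_fusiform",
    "morphology_report",
    "relative_increase",
]

DEFAULT_N_RAYS = 360
DEFAULT_SPACING = 0.25  # mm
HUBER_RATIO = 1.5
REGION_EXTENSION_RATIO = 1.1


class SectionError(ValueError):
    """A cross-section could not be computed at a station."""


@dataclasses.dataclass
class CrossSection:
    s: float
    hit_points: np.ndarray  # (n_rays, 3) ordered boundary samples
    area: float

    @property
    def d_eq(self) -> float:
        return equivalent_diameter(self.area)


@dataclasses.dataclass
class CrossSectionProfile:
    stations: list[CrossSection]
    spacing: float
    n_rays: int

    def __post_init__(self):
        s = self.s_values
        if len(s) > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("stations must be strictly increasing in s")

    @property
    def s_values(self) -> np.ndarray:
        return np.array([c.s for c in self.stations])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.stations])

    @property
    def d_eq_values(self) -> np.ndarray:
        return np.array([c.d_eq for c in self.stations])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"s": self.s_values, "CSA": self.areas, "d_eq": self.d_eq_values}
        )


@dataclasses.dataclass
class DilationRegion:
    s_start: float
    s_end: float
    s_max: float
    ratio_max: float

    def __post_init__(self):
        if not (self.s_start < self.s_max < self.s_end):
            raise ValueError("require s_start < s_max < s_end")


@dataclasses.dataclass
class MorphologyReport:
    csa_a: float  # maximal aneurysmal cross-sectional area, mm^2
    csa_pv: float  # parent-vessel cross-sectional area, mm^2
    ri: float  # relative increase, percent (unrounded)

    @property
    def ri_percent(self) -> int:
        """Relative increase rounded to integer percent for reporting."""
        return int(round(self.ri))

    def to_dict(self) -> dict:
        return {
            "CSA_A_mm2": self.csa_a,
            "CSA_PV_mm2": self.csa_pv,
            "RI_percent": self.ri_percent,
            "RI_unrounded": self.ri,
        }


def _ray_hits(mesh: SurfaceMesh, frame: Frame, n_rays: int, plane_tol: float):
    """First-hit distances/points for ``n_rays`` in-plane rays (Moller-Trumbore)."""
    origin = frame.origin
    # prune to triangles crossing the section plane
    dv = (mesh.vertices - origin) @ frame.tangent
    td = dv[mesh.triangles]
    cand = np.flatnonzero((td.min(axis=1) <= plane_tol) & (td.max(axis=1) >= -plane_tol))
    if cand.size == 0:
        raise SectionError("section crosses open boundary")
    tris = mesh.triangles[cand]
    v0 = mesh.vertices[tris[:, 0]]
    e1 = mesh.vertices[tris[:, 1]] - v0
    e2 = mesh.vertices[tris[:, 2]] - v0

    ang = 2.0 * np.pi * np.arange(n_rays) / n_rays
    dirs = np.outer(np.cos(ang), frame.normal1) + np.outer(np.sin(ang), frame.normal2)

    h = np.cross(dirs[:, None, :], e2[None])  # (r, m, 3)
    a = np.einsum("mj,rmj->rm", e1, h)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / a
        svec = origin[None, None, :] - v0[None]
        u = f * np.einsum("rmj,rmj->rm", svec, h)
        q = np.cross(svec, e1[None])
        vpar = f * np.einsum("rmj,rmj->rm", dirs[:, None, :], q)
        t = f * np.einsum("mj,rmj->rm", e2, q)
        tol = 1e-9
        valid = (
            (np.abs(a) > eps)
            & (u >= -tol)
            & (vpar >= -tol)
            & (u + vpar <= 1.0 + tol)
            & (t > 1e-9)
        )
    t = np.where(valid, t, np.inf)
    best = np.argmin(t, axis=1)
    t_best = t[np.arange(n_rays), best]
    if not np.all(np.isfinite(t_best)):
        raise SectionError("section crosses open boundary")
    # outward-oriented surface: a front hit from inside has negative
    # Moller-Trumbore determinant (a = e1.(dir x e2) = -dir.normal)
    facing = a[np.arange(n_rays), best]
    if np.any(facing >= 0):
        raise SectionError("origin not interior")
    return t_best, origin + t_best[:, None] * dirs


def cross_section_area(
    mesh: SurfaceMesh, frame: Frame, n_rays: int = DEFAULT_N_RAYS
) -> CrossSection:
    """Ray-cast lumen cross-section in the plane perpendicular to the tangent."""
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8")
    # plane slab tolerance: longest triangle extent guard
    plane_tol = 1e-9 + float(
        np.max(np.linalg.norm(mesh.vertices[mesh.triangles[:, 1]] -
                              mesh.vertices[mesh.triangles[:, 0]], axis=1))
    )
    _, pts = _ray_hits(mesh, frame, n_rays, plane_tol)
    rel = pts - frame.origin
    nxt = np.roll(rel, -1, axis=0)
    area = 0.5 * float(np.sum(np.linalg.norm(np.cross(rel, nxt), axis=1)))
    # station value is set by the caller (csa_profile); standalone use gets 0
    return CrossSection(s=0.0, hit_points=pts, area=area)


def csa_profile(
    mesh: SurfaceMesh,
    cl: Centerline,
    spacing: float = DEFAULT_SPACING,
    n_rays: int = DEFAULT_N_RAYS,
    max_fail_fraction: float = 0.2,
) -> CrossSectionProfile:
    """Cross-sectional area at uniform stations along the centerline.

    Stations within one ``spacing`` of the centerline ends are skipped, as are
    stations whose section fails (near open boundaries); failures beyond
    ``max_fail_fraction`` of the attempted stations raise.
    """
    rs = resample_centerline(cl, spacing)
    sections: list[CrossSection] = []
    attempted = failed = 0
    total = rs.total_length
    for s in rs.arc_length:
        if s < spacing - 1e-9 or s > total - spacing + 1e-9:
            continue
        attempted += 1
        try:
            cs = cross_section_area(mesh, rs.frame_at(s), n_rays)
        except SectionError as exc:
            failed += 1
            logger.info("station s=%.3f skipped: %s", s, exc)
            continue
        cs.s = float(s)
        sections.append(cs)
    if attempted == 0 or failed > max_fail_fraction * attempted:
        raise ValueError("centerline/mesh mismatch")
    return CrossSectionProfile(stations=sections, spacing=spacing, n_rays=n_rays)


def nominal_diameter(
    profile: CrossSectionProfile,
    proximal_window: float,
    distal_window: float,
) -> float:
    """Median equivalent diameter over proximal+distal healthy windows."""
    s = profile.s_values
    d = profile.d_eq_values
    lo, hi = s[0], s[-1]
    mask = (s <= lo + proximal_window) | (s >= hi - distal_window)
    if not np.any(mask):
        raise ValueError("empty reference windows")
    return float(np.median(d[mask]))


def detect_fusiform(
    profile: CrossSectionProfile,
    d_nominal: float,
    huber_ratio: float = HUBER_RATIO,
) -> DilationRegion | None:
    """Locate the dominant supra-threshold dilation, if any.

    The maximal contiguous run of stations with ``d_eq > huber_ratio *
    d_nominal`` (largest max CSA among runs) is extended outward to where
    ``d_eq`` first falls below ``1.1 * d_nominal``.
    """
    if d_nominal <= 0:
        raise ValueError("d_nominal must be positive")
    s = profile.s_values
    d = profile.d_eq_values
    above = d > huber_ratio * d_nominal
    if not np.any(above):
        return None
    # contiguous runs of supra-threshold stations
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    if len(runs) > 1:
        logger.info("multiple supra-threshold runs (%d); keeping largest CSA", len(runs))
    areas = profile.areas
    run = max(runs, key=lambda r: areas[r].max())
    i_max = run[np.argmax(areas[run])]
    ext = REGION_EXTENSION_RATIO * d_nominal
    i_lo = run[0]
    while i_lo > 0 and d[i_lo] >= ext:
        i_lo -= 1
    i_hi = run[-1]
    while i_hi < len(d) - 1 and d[i_hi] >= ext:
        i_hi += 1
    return DilationRegion(
        s_start=float(s[i_lo]),
        s_end=float(s[i_hi]),
        s_max=float(s[i_max]),
        ratio_max=float(d[i_max] / d_nominal),
    )


def relative_increase(csa_a: float, csa_pv: float) -> float:
    """Relative increase of an area over a reference, in percent."""
    if csa_a <= 0 or csa_pv <= 0:
        raise ValueError("areas must be positive")
    return 100.0 * csa_a / csa_pv


def morphology_report(
    profile: CrossSectionProfile,
    region: DilationRegion,
    reference: str = "proximal",
) -> MorphologyReport:
    """Maximal dilated area, parent-vessel reference area and relative increase.

    The parent-vessel area is taken at the station immediately proximal to the
    region boundary; ``reference="proximal_window"`` averages over all stations
    proximal to the region instead.
    """
    s = profile.s_values
    areas = profile.areas
    in_region = (s >= region.s_start - 1e-9) & (s <= region.s_end + 1e-9)
    if not np.any(in_region):
        raise ValueError("region not within profile")
    csa_a = float(areas[in_region].max())
    proximal = np.flatnonzero(s < region.s_start - 1e-9)
    if proximal.size == 0:
        raise ValueError("no proximal reference")
    if reference == "proximal":
        csa_pv = float(areas[proximal[-1]])
    elif reference == "proximal_window":
        csa_pv = float(areas[proximal].mean())
    else:
        raise ValueError(f"unknown reference policy: {reference}")
    return MorphologyReport(csa_a=csa_a, csa_pv=csa_pv, ri=relative_increase(csa_a, csa_pv))
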