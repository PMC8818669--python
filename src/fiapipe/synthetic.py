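"""Synthetic inputs with known ground truth.

* parametric tubular vessels (straight / arc / helix centerlines) with an
  optional Gaussian circumferential dilation,
* a representative two-harmonic cardiac waveform,
* analytic pulsatile (Womersley) velocity and wall-shear fields in a rigid
  straight tube, emitted over two cycles so the discard-first-cycle adapter
  is exercised.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import jv

from .flow_bc import Waveform
from .geometry import Centerline, SurfaceMesh
from .indices import VolumeSeries, WallSeries

__all__ = [
    "VesselSpec",
    "PulsatileSpec",
    "make_vessel",
    "tube_mesh",
    "reference_waveform",
    "womersley_fields",
    "three_state_fields",
]

BLOOD_DENSITY = 1055.0  # kg/m^3
BLOOD_VISCOSITY = 4e-3  # Pa*s (dynamic)


@dataclasses.dataclass(frozen=True)
class VesselSpec:
    """Parametric tubular vessel with an optional Gaussian dilation.

    ``kind`` selects the centerline: "straight" (along +z, ``length`` mm),
    "arc" (circle of radius ``bend_radius`` spanning ``length`` of arc) or
    "helix" (``bend_radius``, ``helix_pitch`` per turn, ``length`` of arc).
    """

    length: float = 30.0
    base_radius: float = 2.0
    kind: str = "straight"
    bend_radius: float = 20.0
    helix_pitch: float = 10.0
    dilation_center: float | None = None
    dilation_peak_radius: float = 3.2
    dilation_sigma: float = 3.0
    taper_rate: float = 0.0  # dr/ds, negative tapers distally
    edge_length: float = 0.3

    def __post_init__(self):
        if self.length <= 0 or self.base_radius <= 0:
            raise ValueError("length and base radius must be positive")
        if self.dilation_sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.edge_length >= self.base_radius / 4.0:
            raise ValueError("edge length must be < base_radius/4")
        if self.kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown centerline kind: {self.kind}")
        if self.kind in ("arc", "helix") and self.bend_radius <= self.max_radius():
            raise ValueError("self-intersecting spec: bend radius below peak radius")

    def max_radius(self) -> float:
        r = self.base_radius
        if self.dilation_center is not None:
            r = max(r, self.dilation_peak_radius)
        return r

    def radius_at(self, s) -> np.ndarray:
        """Ground-truth lumen radius r(s)."""
        s = np.asarray(s, dtype=float)
        r = self.base_radius + self.taper_rate * s
        if self.dilation_center is not None:
            bump = (self.dilation_peak_radius - self.base_radius) * np.exp(
                -((s - self.dilation_center) ** 2) / (2.0 * self.dilation_sigma**2)
            )
            r = r + bump
        return r

    def healthy_radius_at(self, s) -> np.ndarray:
        """Radius of the same vessel without the dilation."""
        s = np.asarray(s, dtype=float)
        return self.base_radius + self.taper_rate * s

    def centerline_points(self, spacing: float) -> np.ndarray:
        n = max(2, int(round(self.length / spacing)) + 1)
        s = np.linspace(0.0, self.length, n)
        if self.kind == "straight":
            return np.column_stack([np.zeros(n), np.zeros(n), s])
        if self.kind == "arc":
            phi = s / self.bend_radius
            return np.column_stack(
                [self.bend_radius * (1 - np.cos(phi)), np.zeros(n),
                 self.bend_radius * np.sin(phi)]
            )
        # helix: arc length s along the curve
        rr, p = self.bend_radius, self.helix_pitch
        c = p / (2 * math.pi)
        speed = math.hypot(rr, c)
        phi = s / speed
        return np.column_stack([rr * np.cos(phi), rr * np.sin(phi), c * phi])


def tube_mesh(
    cl: Centerline,
    radius_fn,
    edge_length: float,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> SurfaceMesh:
    """Surface of revolution about a centerline.

    ``radius_fn(s, theta)`` gives the wall distance from the centerline;
    optional seeded vertex jitter (fraction of ``edge_length``, <= 0.05)
    perturbs interior vertices for robustness testing.
    """
    s_all = cl.arc_length
    total = cl.total_length
    n_ax = max(2, int(round(total / edge_length)) + 1)
    s_rings = np.linspace(0.0, total, n_ax)
    r_max = float(np.max(radius_fn(s_rings, 0.0)))
    n_th = max(8, int(round(2 * math.pi * r_max / edge_length)))
    theta = 2 * math.pi * np.arange(n_th) / n_th

    verts = np.empty((n_ax * n_th, 3))
    for i, s in enumerate(s_rings):
        fr = cl.frame_at(s)
        r = np.asarray(radius_fn(np.full(n_th, s), theta), dtype=float)
        ring = (
            fr.origin
            + np.outer(r * np.cos(theta), fr.normal1)
            + np.outer(r * np.sin(theta), fr.normal2)
        )
        verts[i * n_th : (i + 1) * n_th] = ring

    if jitter > 0:
        if jitter > 0.05:
            raise ValueError("jitter limited to 5% of edge length")
        if rng is None:
            rng = np.random.default_rng(0)
        disp = rng.uniform(-1, 1, size=verts.shape) * jitter * edge_length
        disp[:n_th] = 0.0
        disp[-n_th:] = 0.0  # keep boundary rings planar
        verts = verts + disp

    tris = []
    for i in range(n_ax - 1):
        a = i * n_th + np.arange(n_th)
        b = (i + 1) * n_th + np.arange(n_th)
        an = i * n_th + (np.arange(n_th) + 1) % n_th
        bn = (i + 1) * n_th + (np.arange(n_th) + 1) % n_th
        # outward orientation: CCW seen from outside
        tris.append(np.column_stack([a, an, b]))
        tris.append(np.column_stack([an, bn, b]))
    mesh = SurfaceMesh(verts, np.concatenate(tris))
    return mesh


def make_vessel(spec: VesselSpec, seed: int = 0, jitter: float = 0.0):
    """Generate a vessel fixture: (mesh, centerline, ground-truth radius fn)."""
    rng = np.random.default_rng(seed)
    cl = Centerline(spec.centerline_points(spacing=min(0.25, spec.edge_length)))
    mesh = tube_mesh(
        cl,
        lambda s, theta: spec.radius_at(s),
        spec.edge_length,
        rng=rng,
        jitter=jitter,
    )
    return mesh, cl, spec.radius_at


def reference_waveform(
    period: float = 1.0,
    profile: str = "two_harmonic_cardiac",
    mean_flow: float = 5.0,
    a1: float = 0.4,
    a2: float = 0.15,
    phi1: float = 0.0,
    phi2: float = math.pi / 4,
    n_samples: int = 100,
    area: float | None = None,
) -> Waveform:
    """Synthetic stand-in for a representative cardiac inflow waveform.

    Q(t) = Q0 * (1 + a1*sin(2*pi*t/T + phi1) + a2*sin(4*pi*t/T + phi2)).
    This is an artifact default, not a measured waveform.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if profile != "two_harmonic_cardiac":
        raise ValueError(f"unknown waveform profile: {profile}")
    t = period * np.arange(n_samples) / n_samples
    q = mean_flow * (
        1.0
        + a1 * np.sin(2 * math.pi * t / period + phi1)
        + a2 * np.sin(4 * math.pi * t / period + phi2)
    )
    if np.any(q <= 0):
        raise ValueError("waveform parameters drive flow non-positive")
    return Waveform(times=t, values=q, period=period, area=area)


@dataclasses.dataclass(frozen=True)
class PulsatileSpec:
    """Pulsatile tube flow: mean flow plus sinusoidal flow harmonics.

    ``harmonics`` is a list of ``(n, amplitude_fraction, phase)`` tuples; the
    flow of harmonic n is ``amp*Q0*cos(2*pi*n*t/T + phase)``.
    """

    radius: float = 2.0  # mm
    period: float = 1.0  # s
    mean_flow: float = 5.0  # mL/s
    harmonics: tuple = ((1, 0.4, 0.0),)
    rho: float = BLOOD_DENSITY
    mu: float = BLOOD_VISCOSITY

    def __post_init__(self):
        if self.mean_flow <= 0:
            raise ValueError("mean flow must be positive")
        if self.radius <= 0 or self.period <= 0:
            raise ValueError("radius and period must be positive")

    def alpha(self, n: int = 1) -> float:
        """Womersley number R*sqrt(n*omega*rho/mu) for harmonic n."""
        omega = 2 * math.pi * n / self.period
        return (self.radius * 1e-3) * math.sqrt(omega * self.rho / self.mu)

    def flow_at(self, t) -> np.ndarray:
        """Prescribed volumetric flow Q(t), mL/s."""
        t = np.asarray(t, dtype=float)
        q = np.full_like(t, self.mean_flow)
        for n, amp, phase in self.harmonics:
            q = q + amp * self.mean_flow * np.cos(2 * math.pi * n * t / self.period + phase)
        return q


def _womersley_profile(alpha: float, r_over_R: np.ndarray) -> np.ndarray:
    """Complex velocity shape for unit complex flow amplitude over unit area.

    u_hat(r) for Q_hat = 1 over an area of 1 (multiply by Q_hat/(pi R^2)).
    """
    lam = 1j**1.5 * alpha
    j0l = jv(0, lam)
    denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0l)
    return (1.0 - jv(0, lam * r_over_R) / j0l) / denom


def _womersley_wall_shear(alpha: float) -> complex:
    """Complex wall shear for unit complex flow amplitude, times R^3*pi/mu.

    tau_hat = mu * (-du/dr)|_R = (Q_hat*mu/(pi R^3)) * value returned here.
    """
    lam = 1j**1.5 * alpha
    j0l = jv(0, lam)
    denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0l)
    return lam * jv(1, lam) / j0l / denom


def womersley_fields(
    spec: PulsatileSpec,
    n_r: int = 24,
    n_theta: int = 16,
    timesteps_per_cycle: int = 32,
    n_cycles: int = 2,
    axis: np.ndarray | None = None,
) -> tuple[VolumeSeries, WallSeries]:
    """Analytic pulsatile velocity/WSS fields in a rigid straight tube.

    The volume field samples a polar grid on one cross-section (velocities in
    m/s along the tube axis); the wall field samples ``n_theta`` wall elements
    with the analytic shear vector (Pa).  ``n_cycles`` full cycles are
    emitted (default two) so that discard-first-cycle handling is testable.
    """
    if timesteps_per_cycle < 16:
        raise ValueError("need at least 16 timesteps per cycle")
    for n, _, _ in spec.harmonics:
        a = spec.alpha(n)
        if not 0 < a <= 50:
            raise ValueError(f"Womersley number {a:.2f} outside validated range (0, 50]")
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)

    R_m = spec.radius * 1e-3
    area = math.pi * R_m**2
    q_scale = 1e-6  # mL/s -> m^3/s
    mu, T = spec.mu, spec.period

    # polar sampling grid (cell-centered in r for quadrature-friendly weights)
    r_frac = (np.arange(n_r) + 0.5) / n_r
    theta = 2 * math.pi * np.arange(n_theta) / n_theta
    rr, tt = np.meshgrid(r_frac, theta, indexing="ij")
    e1 = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = e1 - (e1 @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    pts = (
        (rr * np.cos(tt)).ravel()[:, None] * e1 * spec.radius
        + (rr * np.sin(tt)).ravel()[:, None] * e2 * spec.radius
    )
    # per-point quadrature weights: dA = r dr dtheta, r = rr*R (m^2)
    w_cell = rr.ravel() * R_m * (R_m / n_r) * (2 * math.pi / n_theta)

    n_t = timesteps_per_cycle * n_cycles
    times = np.arange(n_t) * T / timesteps_per_cycle
    r_flat = rr.ravel()

    # steady (Poiseuille) part
    u_mean = (
        2.0 * spec.mean_flow * q_scale / area * (1.0 - r_flat**2)
    )  # m/s
    tau_mean = 4.0 * mu * spec.mean_flow * q_scale / (math.pi * R_m**3)  # Pa

    u = np.tile(u_mean, (n_t, 1)).astype(float)
    tau = np.full((n_t, n_theta), tau_mean, dtype=float)
    for n, amp, phase in spec.harmonics:
        alpha_n = spec.alpha(n)
        q_hat = amp * spec.mean_flow * q_scale * np.exp(1j * phase)
        shape = _womersley_profile(alpha_n, r_flat)
        tau_hat = q_hat * mu / (math.pi * R_m**3) * _womersley_wall_shear(alpha_n)
        phase_t = np.exp(1j * 2 * math.pi * n * times / T)
        u += np.real(phase_t[:, None] * (q_hat / area * shape)[None, :])
        tau += np.real(phase_t[:, None] * tau_hat)

    vel = u[:, :, None] * axis[None, None, :]
    vs = VolumeSeries(
        points=pts, vectors=vel, times=times, period=T, weights=w_cell, rho=spec.rho
    )

    wall_pts = (
        np.cos(theta)[:, None] * e1 * spec.radius
        + np.sin(theta)[:, None] * e2 * spec.radius
    )
    wall_vec = tau[:, :, None] * axis[None, None, :]
    wall_w = np.full(n_theta, 2 * math.pi * R_m / n_theta)
    ws = WallSeries(
        points=wall_pts, vectors=wall_vec, times=times, period=T, weights=wall_w
    )
    return vs, ws


def three_state_fields(seed: int = 0, **kw):
    """Analytic field triplet emulating fusiform / healthy / treated states.

    The fusiform state carries a strong zero-mean oscillatory harmonic (high
    OSI/OVI); the treated state damps it most of the way back to the healthy
    level.  All three share the same sampling grid.
    """
    rng = np.random.default_rng(seed)
    base = dict(radius=2.0, period=1.0, mean_flow=5.0)
    base.update(kw)
    jitter = 0.02 * rng.standard_normal(3)  # small seeded variation per case
    specs = {
        "healthy": PulsatileSpec(**base, harmonics=((1, 0.25 + jitter[0] * 0.1, 0.0),)),
        "fusiform": PulsatileSpec(
            **base,
            harmonics=((1, 0.3, 0.0), (2, 2.4 + abs(jitter[1]), math.pi / 3)),
        ),
        "treated": PulsatileSpec(
            **base,
            harmonics=((1, 0.28, 0.0), (2, 0.9 + abs(jitter[2]) * 0.1, math.pi / 3)),
        ),
    }
    return {k: womersley_fields(v) for k, v in specs.items()}
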