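"""Shear- and flow-related hemodynamic indices over one cardiac cycle.

All time integrals use trapezoidal quadrature with periodic closure: the
first sample is appended at ``t0 + T`` before integrating, making the
indices invariant under cyclic shifts of the timestep ordering.

Degenerate denominators are defined here explicitly: OSI/OVI are 0 where the
shear/velocity magnitude integral vanishes, and RRT is capped at ``1/eps``
(flagged) where ``(1 - 2*OSI) * AWSS`` falls below ``eps``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "WallSeries",
    "VolumeSeries",
    "IndexField",
    "awss",
    "osi",
    "rrt",
    "ovi",
    "kinetic_energy",
    "index_summary",
    "last_cycle",
]

RRT_EPS = 1e-9  # Pa


@dataclasses.dataclass
class IndexField:
    """Per-element (or per-point) scalar field with a name and units."""

    name: str
    units: str
    values: np.ndarray
    flags: np.ndarray | None = None  # True where a degenerate cap was applied


@dataclasses.dataclass
class _VectorSeries:
    points: np.ndarray  # (n, 3) element centers / sample points
    vectors: np.ndarray  # (n_t, n, 3)
    times: np.ndarray  # (n_t,)
    period: float
    weights: np.ndarray | None = None  # element areas / point volumes

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vector series must be (n_t, n, 3)")
        if self.vectors.shape[1] != len(self.points):
            raise ValueError("element set does not match vector field")
        if self.vectors.shape[0] != len(self.times):
            raise ValueError("times do not match timesteps")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.points):
                raise ValueError("weights do not match points")

    @property
    def n_steps(self) -> int:
        return len(self.times)


@dataclasses.dataclass
class WallSeries(_VectorSeries):
    """Time-resolved wall shear stress vectors (Pa) on wall element centers."""


@dataclasses.dataclass
class VolumeSeries(_VectorSeries):
    """Time-resolved velocity vectors (m/s) at volume sample points."""

    rho: float = 1055.0  # kg/m^3

    def __post_init__(self):
        super().__post_init__()
        if self.rho <= 0:
            raise ValueError("density must be positive")


def _periodic(series: _VectorSeries):
    """Times/values closed over one period for trapezoidal integration."""
    t = series.times
    v = series.vectors
    span = t[-1] - t[0]
    if span > series.period + 1e-9:
        raise ValueError("series spans more than one period; window it first")
    if span < series.period - 1e-9:
        t = np.concatenate([t, [t[0] + series.period]])
        v = np.concatenate([v, v[:1]], axis=0)
    return t, v


def _check_steps(series: _VectorSeries, minimum: int = 3) -> None:
    if series.n_steps < minimum:
        raise ValueError(f"need at least {minimum} timesteps")


def last_cycle(series: _VectorSeries) -> _VectorSeries:
    """Window a multi-cycle series to its final full period (first discarded)."""
    t_end = series.times[-1]
    # the sample at exactly t_end - T belongs to the previous cycle; periodic
    # closure re-creates it from the first kept sample
    keep = series.times > t_end - series.period + 1e-9
    cut = dataclasses.replace(
        series, vectors=series.vectors[keep], times=series.times[keep]
    )
    return cut


def awss(ws: WallSeries) -> IndexField:
    """Time-averaged wall shear stress magnitude, (1/T) integral |tau| dt."""
    _check_steps(ws)
    t, tau = _periodic(ws)
    mag = np.linalg.norm(tau, axis=2)
    return IndexField(
        name="AWSS", units="Pa", values=np.trapezoid(mag, t, axis=0) / ws.period
    )


def _oscillatory_index(series: _VectorSeries, name: str) -> IndexField:
    _check_steps(series)
    t, vec = _periodic(series)
    mean_vec = np.trapezoid(vec, t, axis=0)
    mag_int = np.trapezoid(np.linalg.norm(vec, axis=2), t, axis=0)
    num = np.linalg.norm(mean_vec, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = 0.5 * (1.0 - num / mag_int)
    val = np.where(mag_int > 0, val, 0.0)
    val = np.clip(val, 0.0, 0.5)
    return IndexField(name=name, units="-", values=val)


def osi(ws: WallSeries) -> IndexField:
    """Oscillatory shear index, 0.5*(1 - |int tau dt| / int |tau| dt)."""
    return _oscillatory_index(ws, "OSI")


def ovi(vs: VolumeSeries) -> IndexField:
    """Oscillatory velocity index: OSI form applied to the velocity field."""
    return _oscillatory_index(vs, "OVI")


def rrt(awss_f: IndexField, osi_f: IndexField, eps: float = RRT_EPS) -> IndexField:
    """Relative residence time, 1 / ((1 - 2*OSI) * AWSS), capped at 1/eps."""
    if awss_f.values.shape != osi_f.values.shape:
        raise ValueError("AWSS and OSI fields do not match")
    denom = (1.0 - 2.0 * osi_f.values) * awss_f.values
    flags = denom < eps
    values = np.where(flags, 1.0 / eps, 1.0 / np.where(flags, 1.0, denom))
    return IndexField(name="RRT", units="1/Pa", values=values, flags=flags)


def kinetic_energy(vs: VolumeSeries) -> tuple[np.ndarray, IndexField]:
    """Kinetic energy density 0.5*rho*|v|^2 (J/m^3).

    Returns the per-timestep fields ``(n_t, n)`` and the time-averaged field.
    """
    ek = 0.5 * vs.rho * np.einsum("tij,tij->ti", vs.vectors, vs.vectors)
    t = vs.times
    if t[-1] - t[0] < vs.period - 1e-9:
        t = np.concatenate([t, [t[0] + vs.period]])
        ek_c = np.concatenate([ek, ek[:1]], axis=0)
    else:
        ek_c = ek
    avg = np.trapezoid(ek_c, t, axis=0) / vs.period
    return ek, IndexField(name="KE", units="J/m^3", values=avg)


def index_summary(
    field: IndexField,
    weights: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> dict:
    """Weighted summary statistics {mean, max, p95, weighted_mean} of a field."""
    v = field.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not np.any(mask):
            raise ValueError("empty mask")
        v = v[mask]
        if weights is not None:
            weights = np.asarray(weights)[mask]
    if weights is None:
        weights = np.ones_like(v)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    cum = np.cumsum(weights[order])
    p95 = float(v[order][np.searchsorted(cum, 0.95 * cum[-1])])
    return {
        "mean": float(v.mean()),
        "max": float(v.max()),
        "p95": p95,
        "weighted_mean": float(np.average(v, weights=weights)),
    }
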