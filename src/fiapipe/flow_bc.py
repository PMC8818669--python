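"""Inflow waveform scaling and outlet flow splitting."""

from __future__ import annotations

import dataclasses

import numpy as np

from .morphology import CrossSectionProfile

__all__ = ["Waveform", "OutletSplit", "scale_inflow", "outlet_split"]


@dataclasses.dataclass
class Waveform:
    """One cardiac period of a volumetric flow-rate waveform.

    ``times`` in seconds spanning [0, T); ``values`` in mL/s; ``area`` is the
    inlet cross-sectional area (mm^2) the waveform belongs to, needed by
    :func:`scale_inflow`.
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    area: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("times must span [0, T)")
        if self.mean_flow <= 0:
            raise ValueError("mean flow must be positive")

    @property
    def mean_flow(self) -> float:
        """Period-averaged flow via periodic trapezoidal integration, mL/s."""
        t = np.concatenate([self.times, [self.times[0] + self.period]])
        q = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(q, t) / self.period)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "Q": self.values})


@dataclasses.dataclass
class OutletSplit:
    outlet_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if np.any(self.fractions <= 0) or np.any(self.fractions >= 1):
            raise ValueError("fractions must be in (0, 1)")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in zip(self.outlet_ids, self.fractions)}


def scale_inflow(
    ref: Waveform,
    inlet_area: float,
    policy: str = "match_mean_velocity",
    ref_area: float | None = None,
) -> Waveform:
    """Scale a representative waveform to a case inlet.

    ``match_mean_velocity`` keeps the reference mean velocity (mean flow over
    area); ``flow_proportional_area`` scales mean flow in proportion to the
    inlet area.  Both reduce to the factor ``inlet_area / ref_area``; the
    normalized waveform shape is unchanged.
    """
    if inlet_area <= 0:
        raise ValueError("inlet area must be positive")
    if ref_area is None:
        ref_area = ref.area
    if ref_area is None or ref_area <= 0:
        raise ValueError("reference waveform area required")
    if policy not in ("match_mean_velocity", "flow_proportional_area"):
        raise ValueError(f"unknown scaling policy: {policy}")
    factor = inlet_area / ref_area
    return Waveform(
        times=ref.times.copy(),
        values=ref.values * factor,
        period=ref.period,
        area=inlet_area,
    )


def outlet_split(
    outlet_profiles: list[CrossSectionProfile],
    method: str = "shape_based",
    exponent: float = 3.0,
    outlet_ids: list[str] | None = None,
) -> OutletSplit:
    """Outlet flow fractions from branch geometry.

    ``murray``: fractions proportional to the terminal equivalent diameter to
    the given exponent.  ``shape_based``: the branch-averaged equivalent
    diameter (mean over the whole distal profile) is used instead of a single
    terminal cross-section.
    """
    if len(outlet_profiles) < 2:
        raise ValueError("need at least 2 outlets")
    if outlet_ids is None:
        outlet_ids = [f"outlet_{i}" for i in range(len(outlet_profiles))]
    diam = []
    for prof in outlet_profiles:
        d = prof.d_eq_values
        if d.size == 0:
            raise ValueError("empty outlet profile")
        if method == "murray":
            diam.append(float(d[-1]))
        elif method == "shape_based":
            diam.append(float(d.mean()))
        else:
            raise ValueError(f"unknown split method: {method}")
    diam = np.array(diam)
    if np.all(diam == 0):
        raise ValueError("all outlet diameters are zero")
    weights = diam**exponent
    return OutletSplit(outlet_ids=outlet_ids, fractions=weights / weights.sum())
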