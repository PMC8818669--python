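import math

import numpy as np
import pytest

from fiapipe.geometry import Centerline
from fiapipe.morphology import CrossSection, CrossSectionProfile
from fiapipe.synthetic import VesselSpec, make_vessel, tube_mesh


@pytest.fixture(scope="session")
def straight_centerline():
    z = np.linspace(0.0, 30.0, 121)
    return Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))


@pytest.fixture(scope="session")
def cylinder_case():
    """Straight tube, radius 2 mm, moderate resolution."""
    spec = VesselSpec(length=20.0, base_radius=2.0, edge_length=0.25)
    mesh, cl, radius_fn = make_vessel(spec, seed=0)
    return mesh, cl, spec


@pytest.fixture(scope="session")
def fusiform_case():
    """Gaussian dilation with apex ratio 1.6, sized so that the detected
    region boundaries sit close to the healthy radius (narrow bump, coarse
    station spacing)."""
    spec = VesselSpec(
        length=30.0,
        base_radius=2.0,
        dilation_center=15.0,
        dilation_peak_radius=3.2,
        dilation_sigma=0.75,
        edge_length=0.25,
    )
    mesh, cl, radius_fn = make_vessel(spec, seed=0)
    return mesh, cl, spec


def analytic_profile(d_eq_fn, length=30.0, spacing=0.5):
    """CrossSectionProfile from an analytic equivalent-diameter function."""
    s = np.arange(spacing, length - spacing / 2, spacing)
    stations = [
        CrossSection(s=float(si), hit_points=np.empty((0, 3)),
                     area=math.pi * (d_eq_fn(si) / 2.0) ** 2)
        for si in s
    ]
    return CrossSectionProfile(stations=stations, spacing=spacing, n_rays=0)


@pytest.fixture
def flat_profile():
    return analytic_profile(lambda s: 4.0)
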