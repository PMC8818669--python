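import math

import numpy as np
import pytest

from fiapipe.stenting import (
    DeployedStent,
    StentSpec,
    apposition_map,
    deploy_stent,
    metal_coverage,
    pitch_at_diameter,
    stent_template,
)
from fiapipe.synthetic import VesselSpec, make_vessel

from conftest import analytic_profile

SPEC_75 = StentSpec(length=20.0, diameter=3.0, n_wires=48, strut_thickness_um=42.0,
                    braid_angle_deg=75.0)


class TestTemplate:
    def test_helix_closed_forms(self):
        assert SPEC_75.nominal_pitch == pytest.approx(2.525, abs=1e-3)
        assert SPEC_75.wire_length_per_turn == pytest.approx(9.757, abs=1e-3)

    def test_points_on_nominal_cylinder(self):
        tpl = stent_template(SPEC_75)
        for wire in tpl.wire_paths:
            r = np.linalg.norm(wire[:, :2], axis=1)
            np.testing.assert_allclose(r, 1.5, atol=1e-9)

    def test_axial_span_is_nominal_length(self):
        tpl = stent_template(SPEC_75)
        z = np.concatenate([w[:, 2] for w in tpl.wire_paths])
        assert z.min() == pytest.approx(0.0, abs=1e-9)
        assert z.max() == pytest.approx(SPEC_75.length, rel=1e-6)

    def test_point_count_scales_with_length(self):
        n20 = len(stent_template(SPEC_75).wire_paths[0])
        spec40 = StentSpec(length=40.0, diameter=3.0, n_wires=48,
                           strut_thickness_um=42.0)
        n40 = len(stent_template(spec40).wire_paths[0])
        assert n40 == pytest.approx(2 * n20, rel=0.02)

    def test_handedness_split(self):
        tpl = stent_template(SPEC_75)
        assert len(tpl.wire_paths) == 48

    @pytest.mark.parametrize(
        "kw",
        [
            dict(length=-1, diameter=3, n_wires=48, strut_thickness_um=42),
            dict(length=20, diameter=3, n_wires=47, strut_thickness_um=42),
            dict(length=20, diameter=3, n_wires=48, strut_thickness_um=-1),
            dict(length=20, diameter=3, n_wires=48, strut_thickness_um=42,
                 braid_angle_deg=95),
        ],
    )
    def test_invalid_spec(self, kw):
        with pytest.raises(ValueError):
            StentSpec(**kw)


@pytest.fixture(scope="module")
def straight_tube_3mm():
    spec = VesselSpec(length=40.0, base_radius=1.5, edge_length=0.25)
    mesh, cl, _ = make_vessel(spec, seed=0)
    return mesh, cl


class TestDeployment:
    def test_nominal_lumen_recovers_nominal_length(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        prof = analytic_profile(lambda s: 3.0, length=40.0, spacing=1.0)
        dep = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0, profile=prof)
        assert dep.deployed_length == pytest.approx(SPEC_75.length, rel=5e-3)

    def test_elongation_closed_form(self):
        p = pitch_at_diameter(SPEC_75, 2.5)
        assert p == pytest.approx(5.789, abs=2e-3)
        assert p / SPEC_75.nominal_pitch == pytest.approx(2.29, rel=1e-2)

    def test_smaller_lumen_longer_deployment(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        lengths = []
        for d in (3.0, 2.8, 2.6):
            prof = analytic_profile(lambda s, d=d: d, length=40.0, spacing=1.0)
            spec = StentSpec(length=10.0, diameter=3.0, n_wires=48,
                             strut_thickness_um=42.0)
            dep = deploy_stent(spec, mesh, cl, s_distal=36.0, profile=prof)
            lengths.append(dep.deployed_length)
        assert lengths[0] < lengths[1] < lengths[2]

    def test_wire_length_conserved(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        spec = StentSpec(length=10.0, diameter=3.0, n_wires=48,
                         strut_thickness_um=42.0)
        tpl = stent_template(spec)
        for d in (3.0, 2.7, 2.5):
            prof = analytic_profile(lambda s, d=d: d, length=40.0, spacing=1.0)
            dep = deploy_stent(spec, mesh, cl, s_distal=36.0, profile=prof)
            assert dep.wire_length == pytest.approx(tpl.wire_length, rel=1e-3)

    def test_pitch_identity_per_turn(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        spec = StentSpec(length=10.0, diameter=3.0, n_wires=48,
                         strut_thickness_um=42.0)
        prof = analytic_profile(lambda s: 2.7, length=40.0, spacing=1.0)
        dep = deploy_stent(spec, mesh, cl, s_distal=36.0, profile=prof)
        lt2 = spec.wire_length_per_turn ** 2
        ident = dep.turn_pitch**2 + (math.pi * dep.turn_diameter) ** 2
        np.testing.assert_allclose(ident, lt2, rtol=1e-9)

    def test_deterministic(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        d1 = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0)
        d2 = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0)
        for w1, w2 in zip(d1.wire_paths, d2.wire_paths):
            assert np.array_equal(w1, w2)

    def test_landing_zone_too_short(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        with pytest.raises(ValueError, match="landing zone"):
            prof = analytic_profile(lambda s: 2.5, length=40.0, spacing=1.0)
            deploy_stent(SPEC_75, mesh, cl, s_distal=20.0, profile=prof)

    def test_s_distal_out_of_range(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        with pytest.raises(ValueError, match="s_distal"):
            deploy_stent(SPEC_75, mesh, cl, s_distal=60.0)

    def test_over_expansion_guard(self):
        with pytest.raises(ValueError, match="over-expansion"):
            pitch_at_diameter(SPEC_75, SPEC_75.max_diameter + 0.01)


class TestApposition:
    def test_apposed_in_matching_lumen(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        dep = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0)
        res = apposition_map(dep, mesh)
        assert res["malapposed_fraction"] == 0.0
        assert res["max_gap_mm"] < 0.25

    def test_malapposed_in_bulge(self):
        spec = VesselSpec(length=40.0, base_radius=1.5, dilation_center=20.0,
                          dilation_peak_radius=2.5, dilation_sigma=3.0,
                          edge_length=0.25)
        mesh, cl, _ = make_vessel(spec, seed=0)
        dep = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0)
        res = apposition_map(dep, mesh)
        assert res["malapposed_fraction"] > 0.0
        assert res["max_gap_mm"] > 0.5  # 5 mm bulge vs 3 mm stent

    def test_gaps_non_negative(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        dep = deploy_stent(SPEC_75, mesh, cl, s_distal=32.0)
        res = apposition_map(dep, mesh)
        assert np.all(res["gaps"] >= -1e-6)


class TestCoverage:
    def _nominal_deployment(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        prof = analytic_profile(lambda s: 3.0, length=40.0, spacing=1.0)
        return deploy_stent(SPEC_75, mesh, cl, s_distal=32.0, profile=prof)

    def test_in_unit_interval(self, straight_tube_3mm):
        dep = self._nominal_deployment(straight_tube_3mm)
        lo, hi = dep.s_span
        cov = metal_coverage(dep, lo + 0.1, hi - 0.1)
        assert 0.0 < cov < 1.0

    def test_linear_in_strut_thickness(self, straight_tube_3mm):
        mesh, cl = straight_tube_3mm
        prof = analytic_profile(lambda s: 3.0, length=40.0, spacing=1.0)
        thin = StentSpec(length=20.0, diameter=3.0, n_wires=16,
                         strut_thickness_um=10.0)
        thick = StentSpec(length=20.0, diameter=3.0, n_wires=16,
                          strut_thickness_um=20.0)
        covs = []
        for sp in (thin, thick):
            dep = deploy_stent(sp, mesh, cl, s_distal=32.0, profile=prof)
            lo, hi = dep.s_span
            covs.append(metal_coverage(dep, lo + 0.1, hi - 0.1))
        assert covs[1] == pytest.approx(2 * covs[0], rel=0.1)

    def test_against_rasterization_oracle(self, straight_tube_3mm):
        # brute-force rasterization of one unrolled braid turn at nominal
        dep = self._nominal_deployment(straight_tube_3mm)
        lo, hi = dep.s_span
        cov = metal_coverage(dep, lo + 0.1, hi - 0.1)

        spec = SPEC_75
        W = math.pi * spec.diameter  # circumference
        H = spec.nominal_pitch
        ts = spec.strut_thickness
        n = 1200
        xs = (np.arange(n) + 0.5) / n * W
        zs = (np.arange(n) + 0.5) / n * H
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        covered = np.zeros_like(X, dtype=bool)
        slope = W / H  # dx per dz along a wire
        half = spec.n_wires // 2
        # perpendicular distance of (x, z) to line x = x0 + sign*slope*z (mod W):
        # a horizontal offset dx is foreshortened by cos(beta)
        for sign in (+1, -1):
            for k in range(half):
                x0 = k * W / half
                dx = (X - x0 - sign * slope * Z) % W
                dx = np.minimum(dx, W - dx)
                d_perp = dx * math.cos(math.radians(spec.braid_angle_deg))
                covered |= d_perp <= ts / 2.0
        oracle = covered.mean()
        assert cov == pytest.approx(oracle, rel=0.1)

    def test_segment_outside_stent(self, straight_tube_3mm):
        dep = self._nominal_deployment(straight_tube_3mm)
        with pytest.raises(ValueError, match="outside"):
            metal_coverage(dep, 0.0, 1.0)
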