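import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fiapipe.indices import (
    IndexField,
    VolumeSeries,
    WallSeries,
    awss,
    index_summary,
    kinetic_energy,
    last_cycle,
    osi,
    ovi,
    rrt,
)


def wall_series(tau_fn, n_t=200, n_e=4, T=1.0):
    """WallSeries from tau_fn(t) -> 3-vector, replicated over n_e elements."""
    times = T * np.arange(n_t) / n_t
    tau = np.array([np.tile(tau_fn(t), (n_e, 1)) for t in times])
    centers = np.zeros((n_e, 3))
    return WallSeries(points=centers, vectors=tau, times=times, period=T)


def volume_series(v_fn, n_t=200, n_p=4, T=1.0, rho=1055.0):
    times = T * np.arange(n_t) / n_t
    v = np.array([np.tile(v_fn(t), (n_p, 1)) for t in times])
    return VolumeSeries(points=np.zeros((n_p, 3)), vectors=v, times=times,
                        period=T, rho=rho)


class TestAwss:
    def test_constant_magnitude(self):
        ws = wall_series(lambda t: np.array([1.5, 0, 0]))
        np.testing.assert_allclose(awss(ws).values, 1.5, rtol=1e-12)

    def test_poiseuille_value(self):
        mu, Q, R = 4e-3, 5e-6, 2e-3
        tau0 = 4 * mu * Q / (math.pi * R**3)
        ws = wall_series(lambda t: np.array([tau0, 0, 0]))
        np.testing.assert_allclose(awss(ws).values, 3.183, rtol=1e-3)

    def test_rectified_sinusoid(self):
        ws = wall_series(lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]),
                         n_t=2000)
        np.testing.assert_allclose(awss(ws).values, 2 / math.pi, rtol=1e-4)

    def test_cyclic_shift_invariant(self):
        rng = np.random.default_rng(0)
        tau = rng.normal(size=(50, 3, 3))
        times = np.arange(50) / 50
        ws1 = WallSeries(points=np.zeros((3, 3)), vectors=tau, times=times, period=1.0)
        k = 17
        tau2 = np.roll(tau, -k, axis=0)
        ws2 = WallSeries(points=np.zeros((3, 3)), vectors=tau2, times=times, period=1.0)
        np.testing.assert_allclose(awss(ws1).values, awss(ws2).values, rtol=1e-9)

    def test_too_few_steps(self):
        with pytest.raises(ValueError):
            awss(wall_series(lambda t: np.array([1.0, 0, 0]), n_t=2))


class TestOsi:
    def test_steady_is_zero(self):
        ws = wall_series(lambda t: np.array([2.0, 0, 0]))
        np.testing.assert_allclose(osi(ws).values, 0.0, atol=1e-12)

    def test_full_reversal_is_half(self):
        ws = wall_series(lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]),
                         n_t=2000)
        np.testing.assert_allclose(osi(ws).values, 0.5, atol=1e-6)

    def test_orthogonal_two_phase(self):
        # tau = x for T/2 then y for T/2 -> 0.5*(1 - sqrt(2)/2)
        ws = wall_series(
            lambda t: np.array([1.0, 0, 0]) if t < 0.5 else np.array([0, 1.0, 0]),
            n_t=4000,
        )
        np.testing.assert_allclose(
            osi(ws).values, 0.5 * (1 - math.sqrt(2) / 2), atol=1e-3
        )

    def test_zero_shear_is_zero(self):
        ws = wall_series(lambda t: np.zeros(3))
        np.testing.assert_allclose(osi(ws).values, 0.0, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(arrays(float, (12, 2, 3), elements=st.floats(-1e3, 1e3)))
    def test_bounds_property(self, tau):
        times = np.arange(12) / 12
        ws = WallSeries(points=np.zeros((2, 3)), vectors=tau, times=times, period=1.0)
        vals = osi(ws).values
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5)


class TestRrt:
    def test_basic_value(self):
        a = IndexField("AWSS", "Pa", np.array([2.0]))
        o = IndexField("OSI", "-", np.array([0.0]))
        np.testing.assert_allclose(rrt(a, o).values, 0.5)

    def test_cap_and_flag_at_half_osi(self):
        a = IndexField("AWSS", "Pa", np.array([2.0]))
        o = IndexField("OSI", "-", np.array([0.5]))
        res = rrt(a, o)
        assert res.values[0] == pytest.approx(1e9)
        assert res.flags[0]

    def test_identity_uncapped(self):
        rng = np.random.default_rng(1)
        a = IndexField("AWSS", "Pa", rng.uniform(0.5, 5.0, 100))
        o = IndexField("OSI", "-", rng.uniform(0.0, 0.45, 100))
        res = rrt(a, o)
        ident = res.values * (1 - 2 * o.values) * a.values
        np.testing.assert_allclose(ident[~res.flags], 1.0, rtol=1e-9)

    def test_mismatched_fields(self):
        with pytest.raises(ValueError):
            rrt(IndexField("AWSS", "Pa", np.ones(3)),
                IndexField("OSI", "-", np.ones(4)))


class TestOvi:
    def test_steady_zero(self):
        vs = volume_series(lambda t: np.array([0.3, 0, 0]))
        np.testing.assert_allclose(ovi(vs).values, 0.0, atol=1e-12)

    def test_zero_mean_oscillation_half(self):
        vs = volume_series(lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]),
                           n_t=2000)
        np.testing.assert_allclose(ovi(vs).values, 0.5, atol=1e-6)

    def test_orthogonal_two_phase(self):
        vs = volume_series(
            lambda t: np.array([1.0, 0, 0]) if t < 0.5 else np.array([0, 1.0, 0]),
            n_t=4000,
        )
        np.testing.assert_allclose(
            ovi(vs).values, 0.5 * (1 - math.sqrt(2) / 2), atol=1e-3
        )


class TestKineticEnergy:
    def test_unit_speed(self):
        vs = volume_series(lambda t: np.array([1.0, 0, 0]))
        ek, avg = kinetic_energy(vs)
        np.testing.assert_allclose(ek, 527.5, rtol=1e-12)
        np.testing.assert_allclose(avg.values, 527.5, rtol=1e-12)

    def test_zero_velocity(self):
        vs = volume_series(lambda t: np.zeros(3))
        _, avg = kinetic_energy(vs)
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-15)

    def test_sinusoidal_time_average(self):
        vs = volume_series(
            lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]), n_t=2000
        )
        _, avg = kinetic_energy(vs)
        np.testing.assert_allclose(avg.values, 0.5 * 1055 / 2, rtol=1e-4)


class TestConvergence:
    def test_halving_timestep_second_order(self):
        def make(n_t):
            return wall_series(
                lambda t: np.array(
                    [2.0 + math.sin(2 * math.pi * t), math.cos(2 * math.pi * t), 0]
                ),
                n_t=n_t,
            )

        coarse = awss(make(64)).values[0]
        fine = awss(make(128)).values[0]
        assert abs(fine - coarse) / fine < 0.005


class TestLastCycle:
    def test_drops_first_cycle(self):
        times = np.arange(64) / 32  # two cycles, T = 1
        tau = np.ones((64, 2, 3))
        tau[:32] *= 100.0  # first cycle garbage
        ws = WallSeries(points=np.zeros((2, 3)), vectors=tau, times=times, period=1.0)
        w = last_cycle(ws)
        assert w.times[0] >= times[-1] - 1.0 - 1e-9
        np.testing.assert_allclose(awss(w).values, math.sqrt(3), rtol=1e-9)


class TestSummary:
    def test_constant_field(self):
        f = IndexField("x", "-", np.full(50, 3.3))
        s = index_summary(f)
        assert all(v == pytest.approx(3.3) for v in s.values())

    def test_uniform_weights_mean(self):
        v = np.arange(10.0)
        s = index_summary(IndexField("x", "-", v), weights=np.ones(10))
        assert s["weighted_mean"] == pytest.approx(v.mean())

    def test_p95_against_sort_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(size=1000)
        s = index_summary(IndexField("x", "-", v))
        order = np.sort(v)
        oracle = order[int(math.ceil(0.95 * len(v))) - 1]
        assert abs(s["p95"] - oracle) < 2.0 / len(v)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            index_summary(IndexField("x", "-", np.ones(5)), mask=np.zeros(5, bool))

    def test_mask_applied(self):
        v = np.array([1.0, 2.0, 100.0])
        s = index_summary(IndexField("x", "-", v), mask=np.array([True, True, False]))
        assert s["max"] == 2.0


class TestValidation:
    def test_mismatched_elements(self):
        with pytest.raises(ValueError):
            WallSeries(points=np.zeros((3, 3)), vectors=np.zeros((5, 4, 3)),
                       times=np.arange(5) / 5, period=1.0)

    def test_more_than_one_period(self):
        ws = WallSeries(points=np.zeros((2, 3)), vectors=np.ones((40, 2, 3)),
                        times=np.arange(40) / 20, period=1.0)
        with pytest.raises(ValueError, match="period"):
            awss(ws)
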