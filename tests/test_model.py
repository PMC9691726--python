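"""Kinetic model: closed forms, parameterizations, chromatin smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exportkinetics.model import (
    ChromatinInput,
    KineticParams,
    analytic_step_response,
    interpolate_chromatin,
    simulate,
    simulate_reparam_effective,
    simulate_reparam_efficiency,
    steady_state,
)

TIMES = np.array([0.0, 5, 10, 15, 20, 25, 30, 45, 60, 75, 90, 120])


def pulse(t):
    return 5.0 + 50.0 * np.exp(-(((t - 20.0) / 15.0) ** 2))


class TestKineticParams:
    def test_rejects_non_positive_rates(self):
        with pytest.raises(ValueError):
            KineticParams(0.0, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            KineticParams(0.1, -1.0, 0.1, 0.1)

    def test_composites_are_consistent(self):
        p = KineticParams(0.2, 0.1, 0.05, 0.01)
        assert p.chromatin_release_efficiency == pytest.approx(2.0)
        assert p.export_efficiency == pytest.approx(0.5)
        assert p.effective_transport == pytest.approx(0.1)
        assert p.half_life == pytest.approx(np.log(2) / 0.01)
        # effective transport = release efficiency * k2'
        assert p.effective_transport == pytest.approx(
            p.chromatin_release_efficiency * p.k2_prime
        )

    def test_alternative_constructors_round_trip(self):
        p = KineticParams(0.7, 0.22, 0.52, 0.017)
        q = KineticParams.from_efficiency(
            p.k2, p.chromatin_release_efficiency, p.export_efficiency, p.k_cyto_deg
        )
        r = KineticParams.from_effective(
            p.k2, p.effective_transport, p.export_efficiency, p.k_cyto_deg
        )
        for other in (q, r):
            assert other.k1_prime == pytest.approx(p.k1_prime)
            assert other.k2_prime == pytest.approx(p.k2_prime)


class TestSteadyState:
    def test_zero_input(self):
        assert steady_state(KineticParams(0.2, 0.1, 0.05, 0.01), 0.0) == (0.0, 0.0)

    def test_worked_example(self):
        # y = k1'x/k2 = 0.2*10/0.1, z = k2' y / kd = 0.05*20/0.01
        y, z = steady_state(KineticParams(0.2, 0.1, 0.05, 0.01), 10.0)
        assert y == pytest.approx(20.0)
        assert z == pytest.approx(100.0)

    def test_linearity_in_k2_prime(self):
        p1 = KineticParams(0.2, 0.1, 0.05, 0.01)
        p2 = KineticParams(0.2, 0.1, 0.10, 0.01)
        y1, z1 = steady_state(p1, 10.0)
        y2, z2 = steady_state(p2, 10.0)
        assert y2 == pytest.approx(y1)
        assert z2 == pytest.approx(2 * z1)


class TestSimulate:
    def test_constant_input_steady_state_is_fixed_point(self):
        p = KineticParams(0.2, 0.1, 0.05, 0.01)
        y, z = simulate(p, 10.0, TIMES, init="steady_state")
        assert np.allclose(y, 20.0, rtol=1e-10)
        assert np.allclose(z, 100.0, rtol=1e-10)

    def test_zero_input_zero_init_stays_zero(self):
        p = KineticParams(0.2, 0.1, 0.05, 0.01)
        y, z = simulate(p, 0.0, TIMES, init=(0.0, 0.0))
        assert np.all(y == 0) and np.all(z == 0)

    def test_matches_analytic_step_response(self):
        rng = np.random.default_rng(7)
        t = np.array([0.0, 1, 5, 20, 60, 120, 400])
        for _ in range(20):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 0.5, size=4)))
            y, z = simulate(p, 10.0, t, init=(0.0, 0.0))
            ya, za = analytic_step_response(p, 10.0, t[1:])
            assert np.max(np.abs(y[1:] - ya) / ya) < 1e-6
            assert np.max(np.abs(z[1:] - za) / za) < 1e-6

    def test_exact_integrator_agrees_with_adaptive_solver(self):
        p = KineticParams(0.4, 0.2, 0.08, 0.02)
        y1, z1 = simulate(p, pulse, TIMES, grid_step=0.25)
        y2, z2 = simulate(p, pulse, TIMES, method="lsoda")
        assert np.allclose(y1, y2, rtol=1e-4)
        assert np.allclose(z1, z2, rtol=1e-4)

    def test_non_negative_trajectories(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 1, size=4)))
            y, z = simulate(p, pulse, TIMES, init="steady_state")
            assert np.all(y >= 0) and np.all(z >= 0)

    def test_long_run_reaches_steady_state_ratio(self):
        p = KineticParams(0.3, 0.15, 0.06, 0.01)
        t = np.array([0.0, 2000.0])
        _, z = simulate(p, 7.0, t, init=(0.0, 0.0))
        assert z[-1] / 7.0 == pytest.approx(p.effective_transport / p.k_cyto_deg, rel=1e-6)


class TestReparameterizations:
    def test_equivalent_parameters_identical_trajectories(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 0.5, size=4)))
            y0, z0 = simulate(p, pulse, TIMES)
            y1, z1 = simulate_reparam_efficiency(
                dict(
                    k2=p.k2,
                    release_efficiency=p.chromatin_release_efficiency,
                    export_efficiency=p.export_efficiency,
                    k_cyto_deg=p.k_cyto_deg,
                ),
                pulse,
                TIMES,
            )
            y2, z2 = simulate_reparam_effective(
                dict(
                    k2=p.k2,
                    effective_transport=p.effective_transport,
                    export_efficiency=p.export_efficiency,
                    k_cyto_deg=p.k_cyto_deg,
                ),
                pulse,
                TIMES,
            )
            denom_y = np.maximum(np.abs(y0), 1e-12)
            denom_z = np.maximum(np.abs(z0), 1e-12)
            assert np.max(np.abs(y1 - y0) / denom_y) < 1e-8
            assert np.max(np.abs(z1 - z0) / denom_z) < 1e-8
            assert np.max(np.abs(y2 - y0) / denom_y) < 1e-8
            assert np.max(np.abs(z2 - z0) / denom_z) < 1e-8

    def test_faster_k2_same_steady_state(self):
        # doubling k2 with the efficiency ratios fixed speeds equilibration
        # but leaves the nucleoplasmic steady state unchanged
        base = dict(release_efficiency=2.0, export_efficiency=0.5, k_cyto_deg=0.01)
        t = np.array([0.0, 2.0, 1000.0])
        y_slow, _ = simulate_reparam_efficiency(dict(k2=0.1, **base), 10.0, t, init=(0.0, 0.0))
        y_fast, _ = simulate_reparam_efficiency(dict(k2=0.2, **base), 10.0, t, init=(0.0, 0.0))
        assert y_fast[1] > y_slow[1]  # faster rise
        assert y_fast[2] == pytest.approx(y_slow[2], rel=1e-6) == pytest.approx(20.0, rel=1e-6)

    def test_zero_input_zero_output(self):
        y, z = simulate_reparam_effective(
            dict(k2=0.2, effective_transport=0.1, export_efficiency=0.5, k_cyto_deg=0.01),
            0.0,
            TIMES,
            init=(0.0, 0.0),
        )
        assert np.all(y == 0) and np.all(z == 0)


class TestAnalyticStepResponse:
    def test_zero_at_time_zero_and_steady_state_at_infinity(self):
        p = KineticParams(0.2, 0.1, 0.05, 0.01)
        y, z = analytic_step_response(p, 10.0, np.array([0.0, 1e7]))
        assert y[0] == 0 and z[0] == 0
        y_ss, z_ss = steady_state(p, 10.0)
        assert y[1] == pytest.approx(y_ss, rel=1e-9)
        assert z[1] == pytest.approx(z_ss, rel=1e-6)

    def test_confluent_equal_rates_continuous(self):
        # k2 == k_cyto_deg handled by the t e^{-kt} limit and continuous in k2
        t = np.array([5.0, 30.0, 90.0])
        p_eq = KineticParams(0.2, 0.05, 0.1, 0.05)
        _, z_eq = analytic_step_response(p_eq, 10.0, t)
        _, z_near = analytic_step_response(KineticParams(0.2, 0.05 * (1 + 1e-7), 0.1, 0.05), 10.0, t)
        assert np.allclose(z_eq, z_near, rtol=1e-5)
        assert np.all(np.isfinite(z_eq)) and np.all(z_eq > 0)


class TestChromatinInterpolation:
    times = np.array([0.0, 5, 10, 15, 20, 25, 30, 45, 60, 75, 90, 120])

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            interpolate_chromatin(np.array([0.0, 5, 10]), np.array([1.0, 2, 3]))

    def test_constant_data_preserved(self):
        ci = interpolate_chromatin(self.times, np.full(self.times.size, 5.0), spar=0.45)
        assert np.allclose(ci.evaluate(np.linspace(0, 120, 50)), 5.0, atol=1e-9)

    def test_small_spar_interpolates(self):
        rng = np.random.default_rng(0)
        vals = 10.0 * np.exp(rng.normal(0, 0.5, self.times.size))
        ci = interpolate_chromatin(self.times, vals, spar=1e-3)
        assert np.allclose(ci.evaluate(self.times), vals, rtol=0.01)

    def test_large_spar_near_linear(self):
        vals = pulse(self.times)
        ci = interpolate_chromatin(self.times, vals, spar=0.999)
        # second differences of log2 curve on a uniform grid ~ 0
        g = ci.log2_curve(np.linspace(0, 120, 25))
        assert np.max(np.abs(np.diff(g, 2))) < 1e-3

    def test_zero_weight_point_is_ignored(self):
        vals = pulse(self.times)
        w = np.ones(self.times.size)
        w[4] = 0.0
        ci_zero = interpolate_chromatin(self.times, vals, spar=0.45, weights=w)
        vals2 = vals.copy()
        vals2[4] = 1e6  # value irrelevant at weight zero
        ci_zero2 = interpolate_chromatin(self.times, vals2, spar=0.45, weights=w)
        q = np.linspace(0, 120, 40)
        assert np.allclose(ci_zero.evaluate(q), ci_zero2.evaluate(q), rtol=1e-9)

    def test_evaluation_clipped_at_zero(self):
        vals = np.array([0.0] * 6 + [100.0] * 6)
        ci = interpolate_chromatin(self.times, vals, spar=0.1, pseudocount_fpkm=0.02)
        assert np.all(ci.evaluate(np.linspace(0, 120, 60)) >= 0)


@settings(max_examples=25, deadline=None)
@given(
    k=st.tuples(*[st.floats(0.01, 2.0) for _ in range(4)]),
    x0=st.floats(0.1, 100.0),
)
def test_steady_state_property(k, x0):
    """z_ss/x0 always equals effective_transport / k_cyto_deg."""
    p = KineticParams(*k)
    y, z = steady_state(p, x0)
    assert z / x0 == pytest.approx(p.effective_transport / p.k_cyto_deg, rel=1e-12)
    assert y / x0 == pytest.approx(p.chromatin_release_efficiency, rel=1e-12)
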