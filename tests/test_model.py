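"""Unit and property tests for the population–sulfide ODE model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfgrowth.model import (
    NOT_REACHED,
    ModelParams,
    SimulationSpec,
    Trajectory,
    balanced_growth_rate,
    density_delta_sweep,
    growth_rate,
    ks_reduction_experiment,
    lag_time,
    simulate,
)
from sulfgrowth.model import _rhs
from sulfgrowth.units import CELLS_PER_OD, UM_PER_FMOLE_PER_ML


class TestGrowthRate:
    def test_zero_substrate_gives_zero(self, reference_params):
        assert growth_rate(0.0, 1e5, reference_params) == 0.0

    def test_at_carrying_capacity_gives_zero(self, reference_params):
        assert growth_rate(100.0, reference_params.K, reference_params) == 0.0

    def test_half_maximal_at_monod_constant(self, reference_params):
        # at s = k_s and x -> 0 the Monod factor is exactly 1/2
        g = growth_rate(reference_params.k_s, 1.0, reference_params)
        assert g == pytest.approx(0.13, rel=1e-4)

    def test_negative_inputs_rejected(self, reference_params):
        with pytest.raises(ValueError):
            growth_rate(-1.0, 1e5, reference_params)
        with pytest.raises(ValueError):
            growth_rate(1.0, -1e5, reference_params)

    @settings(max_examples=200, deadline=None)
    @given(
        s=st.floats(0, 1e4),
        x=st.floats(0, 2e8),
    )
    def test_bounded_and_monotone(self, s, x):
        p = ModelParams(g_max=0.26, k_s=7.1, r=0.39, c=3.0, K=1.6e8)
        g = growth_rate(s, x, p)
        assert 0.0 <= g <= p.g_max
        # nondecreasing in s, nonincreasing in x
        assert growth_rate(s + 1.0, x, p) >= g
        assert growth_rate(s, min(x + 1e6, 2e8), p) <= g + 1e-15


class TestModelParams:
    @pytest.mark.parametrize(
        "bad", [{"g_max": 0.0}, {"k_s": -1.0}, {"K": 0.0}, {"r": -0.1},
                {"c": -1.0}, {"delta": -0.5}]
    )
    def test_invalid_values_rejected(self, reference_params, bad):
        with pytest.raises(ValueError):
            reference_params.replace(**bad)


class TestSimulate:
    def test_sulfide_decays_exponentially_without_sources(self):
        # with r = c = 0 the sulfide equation decouples: s = s0 * exp(-delta t)
        p = ModelParams(g_max=0.26, k_s=7.1, r=0.0, c=0.0, K=1.6e8, delta=0.3)
        traj = simulate(p, SimulationSpec(x0=1.0, s0=50.0, t_end=20.0))
        expected = 50.0 * np.exp(-0.3 * traj.times)
        np.testing.assert_allclose(traj.s, expected, rtol=1e-6)

    def test_exponential_limit_when_substrate_saturating(self, reference_params):
        # s0 >> k_s and x0 << K: Monod and logistic factors ~ 1, so growth
        # is exponential at g_max over 3 doublings to within 1%
        t_end = 3 * math.log(2) / reference_params.g_max
        traj = simulate(
            reference_params, SimulationSpec(x0=1e3, s0=1e4, t_end=t_end)
        )
        expected = 1e3 * np.exp(reference_params.g_max * traj.times)
        np.testing.assert_allclose(traj.x, expected, rtol=0.01)

    def test_sulfide_production_term_unit_arithmetic(self, reference_params):
        # at x = 1e8 cells/ml and r = 0.39 fmole/cell/h, production is
        # 0.39e8 fmole/ml/h = 39 μM/h (with s = 0 there is no growth or loss)
        dxdt, dsdt = _rhs(0.0, np.array([1e8, 0.0]), reference_params)
        assert dxdt == 0.0
        assert dsdt == pytest.approx(39.0, rel=1e-12)

    def test_density_monotone_and_capped_at_K(self, reference_params):
        traj = simulate(reference_params, SimulationSpec(x0=7e6, t_end=300.0))
        assert np.all(np.diff(traj.x) >= -1e-6 * traj.x[:-1])
        assert traj.x.max() <= reference_params.K * (1 + 1e-6)

    def test_mass_balance_closed_system(self, reference_params):
        # with delta = 0: s(t) + c'(x(t)-x0) - s0 = r' * integral of x dt,
        # where primes denote μM-converted per-cell quantities
        spec = SimulationSpec(x0=7e4, s0=5.0, t_end=150.0, n_points=3001)
        traj = simulate(reference_params, spec)
        r_um = reference_params.r * UM_PER_FMOLE_PER_ML
        c_um = reference_params.c * UM_PER_FMOLE_PER_ML
        lhs = traj.s + c_um * (traj.x - spec.x0) - spec.s0
        rhs = r_um * np.concatenate(
            [[0.0], np.cumsum(np.diff(traj.times) * (traj.x[1:] + traj.x[:-1]) / 2)]
        )
        scale = np.maximum(np.abs(rhs), 1e-9)
        assert np.max(np.abs(lhs - rhs) / scale) < 1e-3

    def test_solver_robustness_to_tolerances(self, reference_params):
        lags = []
        for rel, ab in [(1e-8, 1e-10), (5e-9, 5e-11)]:
            traj = simulate(
                reference_params,
                SimulationSpec(x0=7e4, t_end=200.0, n_points=2001,
                               rel_tol=rel, abs_tol=ab),
            )
            lags.append(lag_time(traj, 7e4, balanced_growth_rate(reference_params)))
        assert abs(lags[0] - lags[1]) / lags[0] < 0.005

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(x0=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(x0=1.0, s0=-1.0)
        with pytest.raises(ValueError):
            SimulationSpec(x0=1.0, t_end=0.0)


class TestLagTime:
    def test_pure_exponential_has_zero_lag(self):
        t = np.linspace(0, 20, 201)
        x = 1e5 * np.exp(0.26 * t)
        traj = Trajectory(times=t, x=x, s=np.zeros_like(t))
        assert lag_time(traj, 1e5, 0.26) == pytest.approx(0.0, abs=1e-9)

    def test_saturating_trajectory_never_reaches_threshold(self):
        t = np.linspace(0, 20, 50)
        x = 1e5 * (2.0 - np.exp(-t))  # saturates at 2e5 < 10 * 1e5
        traj = Trajectory(times=t, x=x, s=np.zeros_like(t))
        assert lag_time(traj, 1e5, 0.26) == NOT_REACHED

    def test_lower_inoculum_has_longer_lag(self, reference_params):
        ref = balanced_growth_rate(reference_params)
        lags = {}
        for od in (0.001, 0.1):
            x0 = od * CELLS_PER_OD
            traj = simulate(
                reference_params, SimulationSpec(x0=x0, t_end=200.0, n_points=2001)
            )
            lags[od] = lag_time(traj, x0, ref)
        assert lags[0.001] > lags[0.1] > 0.0

    def test_fold_must_exceed_one(self):
        t = np.linspace(0, 5, 10)
        traj = Trajectory(times=t, x=np.exp(t), s=np.zeros_like(t))
        with pytest.raises(ValueError):
            lag_time(traj, 1.0, 0.26, fold=1.0)


class TestBalancedGrowthRate:
    def test_release_limited_rate_is_r_over_c(self, reference_params):
        assert balanced_growth_rate(reference_params) == pytest.approx(0.13)

    def test_capped_at_g_max(self, reference_params):
        fast = reference_params.replace(r=10.0)  # r/c >> g_max
        assert balanced_growth_rate(fast) == reference_params.g_max
        assert balanced_growth_rate(reference_params.replace(c=0.0)) == reference_params.g_max


class TestDensityDeltaSweep:
    def test_single_cell_matches_lag_time(self, reference_params):
        df = density_delta_sweep(reference_params, [7e5], [0.0], t_end=100.0)
        assert df.shape == (1, 3)
        traj = simulate(reference_params, SimulationSpec(x0=7e5, t_end=100.0,
                                                     n_points=2001))
        direct = lag_time(traj, 7e5, balanced_growth_rate(reference_params))
        assert df["lag_h"].iloc[0] == pytest.approx(direct, rel=1e-6)

    def test_lag_monotone_in_density_and_delta(self, reference_params):
        df = density_delta_sweep(
            reference_params, [0.001, 0.01, 0.1], [0.0, 0.05, 0.1],
            x0_in_od=True, t_end=250.0,
        )
        for d, grp in df.groupby("delta"):
            lags = grp.sort_values("x0")["lag_h"].to_numpy()
            assert np.all(lags[1:] <= lags[:-1]), f"lag not nonincreasing in x0 at δ={d}"
        for x0, grp in df.groupby("x0"):
            lags = grp.sort_values("delta")["lag_h"].to_numpy()
            assert np.all(lags[1:] >= lags[:-1]), f"lag not nondecreasing in δ at x0={x0}"

    def test_lag_increases_with_delta_until_not_reached(self, reference_params):
        df = density_delta_sweep(
            reference_params, [0.001], [0.0, 0.1, 0.2, 0.3], x0_in_od=True
        )
        lags = df["lag_h"].to_numpy()
        finite = lags[np.isfinite(lags)]
        assert np.all(np.diff(finite) > 0)
        assert lags[-1] == NOT_REACHED  # strong loss starves the low inoculum

    def test_empty_grid_rejected(self, reference_params):
        with pytest.raises(ValueError):
            density_delta_sweep(reference_params, [], [0.0])


class TestKsReduction:
    def test_factor_one_changes_nothing(self, reference_params):
        res = ks_reduction_experiment(
            reference_params, factor=1.0, x0_list=[0.01], delta_list=[0.0, 0.1]
        )
        np.testing.assert_allclose(
            res.baseline["lag_h"], res.reduced["lag_h"], rtol=1e-9
        )

    def test_lag_reduction_monotone_in_factor(self, reference_params):
        lags = []
        for factor in (1.0, 2.0, 50.0):
            res = ks_reduction_experiment(
                reference_params, factor=factor, x0_list=[0.001], delta_list=[0.0]
            )
            lags.append(res.reduced["lag_h"].iloc[0])
        assert lags[0] > lags[1] > lags[2] > 0.0

    def test_fifty_fold_collapses_lag_and_delta_sensitivity(self, reference_params):
        res = ks_reduction_experiment(reference_params, factor=50.0)
        base = res.baseline.set_index(["x0", "delta"])["lag_h"]
        red = res.reduced.set_index(["x0", "delta"])["lag_h"]
        for key, lag in red.items():
            assert lag < 0.10 * base.loc[key]  # inf baseline trivially satisfied
        sens_b = res.delta_sensitivity("baseline")
        sens_r = res.delta_sensitivity("reduced")
        assert (sens_r.to_numpy() < sens_b.to_numpy()).all()
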