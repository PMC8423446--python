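import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluctlearn import (OUParams, EpochSchedule, LearningParams,
                        build_anisotropy_matrix, make_regulator_geometry,
                        simulate_demand, simulate_learning, learned_angle,
                        angle_error, gamma_threshold, run_sweep, performance,
                        control_input_power)
from fluctlearn.analysis import responsiveness_empirical
from fluctlearn.circuits import CircuitTrajectory

from conftest import constant_demand


def _circuit_from(demand, P):
    n = demand.times.shape[0]
    return CircuitTrajectory(times=demand.times,
                             a=np.zeros((n, 1)), P=P,
                             x=P / demand.D, epoch_index=demand.epoch_index)


class TestPerformance:
    def test_perfect_tracking_is_zero(self, demand_1d):
        circ = _circuit_from(demand_1d, demand_1d.D.copy())
        assert performance(circ, demand_1d)[0] == 0.0

    def test_frozen_at_mean_recovers_ou_variance(self):
        env = OUParams(dbar=np.ones(1), M=np.array([[1.0]]), gamma=0.05,
                       dt=1e-2)
        demand = simulate_demand(EpochSchedule.single(env, 2e4), seed=17)
        circ = _circuit_from(demand, np.ones_like(demand.D))
        perf = performance(circ, demand, discard=0.2)[0]
        assert perf == pytest.approx(-0.05, rel=0.1)

    def test_never_positive_and_per_epoch(self):
        base = dict(dbar=np.ones(1), M=np.array([[1.0]]), dt=1e-2)
        sched = EpochSchedule(((OUParams(gamma=0.01, **base), 30.0),
                               (OUParams(gamma=0.1, **base), 30.0)))
        demand = simulate_demand(sched, seed=2)
        circ = _circuit_from(demand, np.ones_like(demand.D))
        perf = performance(circ, demand)
        assert perf.shape == (2,)
        assert np.all(perf <= 0)

    def test_misaligned_grids_rejected(self, demand_1d):
        circ = _circuit_from(demand_1d, demand_1d.D.copy())
        other = constant_demand(1.0, duration=10.0)
        with pytest.raises(ValueError, match="misaligned"):
            performance(circ, other)

    def test_invalid_discard_rejected(self, demand_1d):
        circ = _circuit_from(demand_1d, demand_1d.D.copy())
        with pytest.raises(ValueError):
            performance(circ, demand_1d, discard=1.0)

    def test_cip_of_frozen_production_is_zero(self, demand_1d):
        circ = _circuit_from(demand_1d, np.ones_like(demand_1d.D))
        assert control_input_power(circ)[0] == 0.0


class TestLearnedAngle:
    def test_isotropic_is_undefined(self):
        assert np.isnan(learned_angle(np.eye(2)))

    @pytest.mark.parametrize("theta", [0.0, 0.4, np.pi / 2, 2.5])
    def test_rank_one_recovers_direction(self, theta):
        u = np.array([np.cos(theta), np.sin(theta)])
        ang = learned_angle(np.outer(u, u))
        assert abs(angle_error(ang, theta)) < 1e-9

    def test_nonsymmetric_warns(self):
        with pytest.warns(UserWarning, match="symmetriz"):
            learned_angle(np.array([[2.0, 0.5], [0.0, 1.0]]))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            learned_angle(np.eye(3))

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, np.pi), b=st.floats(0, np.pi))
    def test_angle_error_bounded_and_signed(self, a, b):
        e = angle_error(a, b)
        assert -np.pi / 2 - 1e-12 < e <= np.pi / 2 + 1e-12
        assert angle_error(a, a) == 0.0


class TestResponsivenessEmpirical:
    def test_zero_activities_zero_matrix(self):
        p = LearningParams(d=-1.0)
        geom = make_regulator_geometry(4, nx=2)
        est = responsiveness_empirical(np.zeros(4), np.ones(2), geom, p)
        # production floor pins x; derivative vanishes with all a = 0
        assert np.abs(est.matrix).max() < 1e-8

    def test_kink_crossing_is_flagged(self):
        # at x = 1 with d = 0 every drive sits exactly on the kink
        p = LearningParams(d=0.0)
        geom = make_regulator_geometry(2, nx=1)
        est = responsiveness_empirical(np.array([1.5, 0.5]), np.ones(1),
                                       geom, p, delta=1e-4)
        assert est.kink_flagged


class TestGammaThreshold:
    def setup_method(self):
        self.env = OUParams(dbar=np.ones(1), M=np.array([[1.0]]), gamma=0.0,
                            dt=1e-2)
        self.geom = make_regulator_geometry(2, nx=1)

    def test_no_degradation_no_threshold(self, params):
        gm = gamma_threshold(self.geom, params, self.env, kappa=0.0,
                             bracket=(1e-9, 1.0), duration=300.0)
        assert gm == pytest.approx(1e-9)

    def test_threshold_increases_with_kappa(self, params):
        g1 = gamma_threshold(self.geom, params, self.env, kappa=1e-3,
                             duration=1000.0)
        g2 = gamma_threshold(self.geom, params, self.env, kappa=1e-2,
                             duration=1000.0)
        assert 0 < g1 < g2

    def test_aligned_regulator_activates_sooner(self, params):
        # surplus regulator along the soft (dominant-fluctuation) axis
        # versus along the stiff axis
        env = OUParams(dbar=np.ones(2),
                       M=build_anisotropy_matrix(0.0, 10.0, 1.0),
                       gamma=0.0, dt=5e-3)
        aligned = make_regulator_geometry(
            3, nx=2, angles=[0.0, np.pi / 2, np.pi])
        misaligned = make_regulator_geometry(
            3, nx=2, angles=[0.0, np.pi / 2, 3 * np.pi / 2])
        g_al = gamma_threshold(aligned, params, env, kappa=3e-3,
                               duration=800.0)
        g_mis = gamma_threshold(misaligned, params, env, kappa=3e-3,
                                duration=800.0)
        assert g_al < g_mis

    def test_no_surplus_geometry_rejected(self, params):
        geom = make_regulator_geometry(1, nx=1)
        with pytest.raises(ValueError, match="surplus"):
            gamma_threshold(geom, params, self.env, kappa=1e-3)


class TestRunSweep:
    def test_requires_protocol_and_seed(self):
        with pytest.raises(ValueError, match="protocol"):
            run_sweep({"seed": 0})
        with pytest.raises(ValueError, match="seed"):
            run_sweep({"protocol": "variance-epochs"})

    def test_variance_epochs_smoke(self):
        res = run_sweep({"protocol": "variance-epochs", "seed": 0,
                         "gammas": (0.01, 0.05), "epoch_duration": 300.0})
        assert res["perf_learning"].shape == (2,)
        assert np.all(res["perf_learning"] <= 0)
        # mean encoding: activator minus repressor tracks the demand mean
        assert np.allclose(res["a_diff"], 1.0, atol=0.1)

    def test_ablation_grid_shape(self):
        df = run_sweep({"protocol": "ablation-grid", "seed": 0,
                        "na_list": (2, 3), "d_list": (0.0,),
                        "alphas": (0.0,), "duration": 200.0})
        assert set(df.na) == {2, 3}
        assert "gain" in df.columns
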