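import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluctlearn import (LearningParams, make_regulator_geometry, simulate_sepi,
                        simulate_learning, responsiveness_analytic)
from fluctlearn.analysis import responsiveness_empirical
from fluctlearn.circuits import RegulatorGeometry

from conftest import constant_demand


class TestGeometry:
    def test_1d_pair_is_activator_repressor(self):
        g = make_regulator_geometry(2, nx=1)
        assert np.allclose(g.sigma, [[1.0], [-1.0]])

    def test_2d_default_equally_spaced(self):
        g = make_regulator_geometry(4, nx=2)
        assert np.allclose(g.angles, [0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert np.allclose(np.linalg.norm(g.sigma, axis=1), 1.0)

    def test_single_co_activating_regulator(self):
        g = make_regulator_geometry(1, nx=2, angles=[np.pi / 4])
        assert np.allclose(g.sigma, [[np.sqrt(0.5), np.sqrt(0.5)]])

    def test_nx3_unsupported_without_sigma(self):
        with pytest.raises(ValueError):
            make_regulator_geometry(3, nx=3)

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError):
            RegulatorGeometry(sigma=np.array([[1.0, 1.0]]))

    def test_non_spanning_rows_warn(self):
        # both regulators on the x1 axis cannot mean-match (1, 1)
        with pytest.warns(UserWarning, match="positively span"):
            make_regulator_geometry(2, nx=2)  # default angles {0, pi}

    def test_positive_span_check(self):
        g = make_regulator_geometry(5, nx=2)
        assert g.positively_spans()          # full circle spans everything
        quarter = make_regulator_geometry(2, nx=2, angles=[0.0, np.pi / 2])
        assert quarter.positively_spans()
        assert not quarter.positively_spans(np.array([-1.0, 0.0]))


class TestSepi:
    def test_fixed_point_stays_put(self, params):
        circ = simulate_sepi(constant_demand(1.0), params,
                             a0=np.array([1.0]))
        assert np.allclose(circ.x, 1.0)
        assert np.allclose(circ.P, 1.0)

    @pytest.mark.parametrize("a0", [0.3, 2.5])
    def test_converges_to_homeostasis(self, params, a0):
        # analytic fixed point: regulator stationarity forces x = 1, P = D
        circ = simulate_sepi(constant_demand(2.0, duration=600.0), params,
                             a0=np.array([a0]))
        assert circ.x[-1, 0] == pytest.approx(1.0, abs=1e-5)
        assert circ.a[-1, 0] == pytest.approx(2.0, abs=2e-5)

    def test_rejects_nonpositive_demand(self, params):
        demand = constant_demand(1.0)
        object.__setattr__(demand, "D", demand.D - 2.0)
        with pytest.raises(ValueError):
            simulate_sepi(demand, params)


class TestLearningCircuit:
    def test_static_stationary_family(self, geom_pair):
        # kappa = 0, d = 0: any mean-matching state with x = 1 is stationary
        p = LearningParams(kappa=0.0)
        circ = simulate_learning(constant_demand(1.0), geom_pair, p,
                                 a0=np.array([3.0, 2.0]))
        assert np.allclose(circ.a[-1], [3.0, 2.0])
        assert np.allclose(circ.x, 1.0)

    def test_kappa_offset_is_order_kappa(self, geom_pair):
        kappa = 1e-3
        p = LearningParams(kappa=kappa)
        circ = simulate_learning(constant_demand(1.0, duration=2000.0),
                                 geom_pair, p, a0=np.array([1.5, 0.5]))
        off = abs(circ.x[-1, 0] - 1.0)
        assert kappa / 10 < off < 10 * kappa

    def test_activity_floor_holds(self, params, env_1d, demand_1d, geom_pair):
        circ = simulate_learning(demand_1d, geom_pair, params)
        assert np.all(circ.a >= params.a_floor)

    def test_production_is_sigma_weighted_sum(self, params, demand_1d,
                                              geom_pair):
        circ = simulate_learning(demand_1d, geom_pair, params)
        assert np.allclose(circ.P, circ.a @ geom_pair.sigma, atol=2e-3)
        assert np.allclose(circ.x, circ.P / demand_1d.D)

    @settings(max_examples=15, deadline=None)
    @given(dbar=st.floats(0.5, 3.0), na=st.integers(3, 6))
    def test_static_adaptation_2d(self, dbar, na):
        # any constant positive demand is matched exactly as kappa -> 0
        geom = make_regulator_geometry(na, nx=2)
        p = LearningParams(kappa=0.0)
        demand = constant_demand(np.array([dbar, dbar]), nx=2,
                                 duration=800.0)
        circ = simulate_learning(demand, geom, p)
        assert np.allclose(circ.x[-1], 1.0, atol=1e-3)
        assert np.allclose(circ.P[-1], dbar, atol=1e-3 * dbar)


class TestResponsiveness:
    def test_zero_activities_zero_matrix(self, params):
        geom = make_regulator_geometry(5, nx=2)
        R = responsiveness_analytic(np.zeros(5), geom, params)
        assert np.allclose(R, 0.0)

    def test_1d_pair_scales_with_total_activity(self, params, geom_pair):
        # sigma = +-1 makes the responsiveness (a+ + a-)/tau_a
        R = responsiveness_analytic(np.array([2.0, 1.5]), geom_pair, params)
        assert R[0, 0] == pytest.approx(3.5 / params.tau_a)

    def test_symmetric_psd(self, params):
        rng = np.random.default_rng(0)
        geom = make_regulator_geometry(5, nx=2)
        for _ in range(5):
            R = responsiveness_analytic(rng.uniform(0, 3, 5), geom, params)
            assert np.allclose(R, R.T)
            assert np.linalg.eigvalsh(R).min() >= -1e-12

    def test_matches_finite_difference(self):
        # random operating points (x = 1, D = Dbar = 1, all branches on the
        # linear part with d < 0): analytic linearization vs central
        # differences to 1%
        from scipy.linalg import null_space
        from scipy.optimize import nnls

        p = LearningParams(d=-0.5)
        rng = np.random.default_rng(1)
        geom = make_regulator_geometry(5, nx=2)
        base, _ = nnls(geom.sigma.T, np.ones(2))
        N = null_space(geom.sigma.T)
        checked = 0
        while checked < 10:
            a = base + N @ rng.uniform(-0.3, 0.3, N.shape[1])
            if a.min() < 0.01:
                continue
            est = responsiveness_empirical(a, np.ones(2), geom, p, delta=1e-5)
            assert not est.kink_flagged
            Ra = responsiveness_analytic(a, geom, p)
            scale = np.abs(Ra).max()
            assert np.abs(est.matrix - Ra).max() < 0.01 * scale
            checked += 1

    def test_without_self_activation_weights_drop(self, geom_pair):
        p = LearningParams(self_activation=False)
        R = responsiveness_analytic(np.array([5.0, 1.0]), geom_pair, p)
        assert R[0, 0] == pytest.approx(2.0 / p.tau_a)


def test_circuit_csv_roundtrip(tmp_path, params, geom_pair, demand_1d):
    from fluctlearn import write_circuit_csv, read_circuit_csv

    circ = simulate_learning(demand_1d, geom_pair, params)
    path = write_circuit_csv(circ, tmp_path / "circ.csv", params=params)
    back = read_circuit_csv(path)
    assert np.allclose(back.a, circ.a)
    assert np.allclose(back.P, circ.P)
    assert np.allclose(back.x, circ.x)
    assert back.p_floor_count == circ.p_floor_count
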