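"""Summary statistics and sweep experiments for the circuit simulations.

Provides the performance functional (negated mean-squared tracking error),
the Control Input Power of a simulated trajectory, empirical and analytic
responsiveness with the learned angle, the minimal fluctuation strength at
which learning engages, and the canonical sweep protocols (variance epochs,
angle epochs, Γ sweep, anisotropy sweep, ablation grid, biochemical
epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import (OUParams, EpochSchedule, DemandTrajectory,
                          build_anisotropy_matrix, simulate_demand)
from .circuits import (RegulatorGeometry, LearningParams, CircuitTrajectory,
                       PRODUCTION_FLOOR, make_regulator_geometry,
                       simulate_sepi, simulate_learning,
                       responsiveness_analytic)
from . import biochem
from . import optimal_control as oc

__all__ = [
    "PerformanceReport",
    "ResponsivenessEstimate",
    "performance",
    "control_input_power",
    "homeostatic_error",
    "responsiveness_empirical",
    "learned_angle",
    "angle_error",
    "gamma_threshold",
    "run_sweep",
    "protocol_variance_epochs",
    "protocol_angle_epochs",
    "protocol_angle_recovery",
    "protocol_gamma_sweep",
    "protocol_anisotropy_sweep",
    "protocol_ablation_grid",
    "protocol_biochem_epochs",
]

#: default fraction of each epoch discarded as adaptation transient.
DEFAULT_DISCARD = 0.3

#: angles the ablation grid averages over.
ABLATION_ALPHAS = (0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8, np.pi / 2)


@dataclass
class PerformanceReport:
    """Per-epoch performance / effort summary of one simulation."""

    performance: np.ndarray          # per-epoch, always <= 0
    cip: np.ndarray                  # per-epoch control input power
    discard: float
    seed: int
    provenance: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "performance": np.asarray(self.performance).tolist(),
            "cip": np.asarray(self.cip).tolist(),
            "discard": self.discard,
            "seed": self.seed,
            "provenance": self.provenance,
            "extras": {k: np.asarray(v).tolist() for k, v in self.extras.items()},
        }


@dataclass
class ResponsivenessEstimate:
    """Responsiveness matrix with its dominant direction."""

    matrix: np.ndarray
    method: str                       # "analytic" | "finite-difference"
    learned_angle: float              # radians in [0, pi), nan if undefined
    eigen_gap: float
    kink_flagged: bool = False


def _epoch_slices(epoch_index: np.ndarray, discard: float):
    if not 0 <= discard < 1:
        raise ValueError("discard must be in [0, 1)")
    n_epochs = int(epoch_index.max()) + 1
    for e in range(n_epochs):
        idx = np.flatnonzero(epoch_index == e)
        start = idx[0] + int(discard * idx.size)
        yield slice(start, idx[-1] + 1)


def _check_aligned(circuit: CircuitTrajectory, demand: DemandTrajectory) -> None:
    if circuit.times.shape != demand.times.shape or \
            not np.array_equal(circuit.times, demand.times):
        raise ValueError("circuit and demand grids are misaligned")


def performance(circuit: CircuitTrajectory, demand: DemandTrajectory,
                discard: float = DEFAULT_DISCARD) -> np.ndarray:
    """Per-epoch performance ``-<sum_i (P_i - D_i)^2>``.

    The first ``discard`` fraction of each epoch is dropped as adaptation
    transient.  Perfect tracking gives 0; the value is never positive.
    """
    _check_aligned(circuit, demand)
    err2 = np.sum((circuit.P - demand.D) ** 2, axis=1)
    return np.array([-err2[s].mean()
                     for s in _epoch_slices(demand.epoch_index, discard)])


def control_input_power(circuit: CircuitTrajectory,
                        discard: float = DEFAULT_DISCARD) -> np.ndarray:
    """Per-epoch Control Input Power ``(1/T) int ||dP/dt||^2 dt``.

    ``dP/dt`` is taken by first differences on the simulation grid within
    the retained part of each epoch.
    """
    dt = circuit.dt
    out = []
    for s in _epoch_slices(circuit.epoch_index, discard):
        dP = np.diff(circuit.P[s], axis=0) / dt
        out.append(np.sum(dP ** 2, axis=1).mean())
    return np.array(out)


def homeostatic_error(circuit: CircuitTrajectory, setpoint: float = 1.0,
                      discard: float = DEFAULT_DISCARD) -> np.ndarray:
    """Per-epoch mean-squared deviation of the metabolite from its set point."""
    err2 = np.sum((circuit.x - setpoint) ** 2, axis=1)
    return np.array([err2[s].mean()
                     for s in _epoch_slices(circuit.epoch_index, discard)])


# ---------------------------------------------------------------------------
# responsiveness


def _production_rate_of_change(a: np.ndarray, D: np.ndarray,
                               geometry: RegulatorGeometry,
                               params: LearningParams):
    """Instantaneous (dP/dt, drive branch pattern) of the learning circuit."""
    s = geometry.sigma
    P = np.maximum(s.T @ a, PRODUCTION_FLOOR)
    x = P / D
    g = s @ (1.0 - x)
    active = g > params.d
    gm = np.maximum(g, params.d)
    if params.self_activation:
        adot = (a * gm - params.kappa * a) / params.tau_a
    else:
        adot = (gm - params.kappa * a) / params.tau_a
    return s.T @ adot, active


def responsiveness_empirical(a: np.ndarray, D: np.ndarray,
                             geometry: RegulatorGeometry,
                             params: LearningParams,
                             delta: float = 1e-4) -> ResponsivenessEstimate:
    """Finite-difference responsiveness ``R_ij = d(dP_i/dt)/dD_j``.

    Central differences of the instantaneous production rate-of-change with
    respect to each demand component.  If the perturbation crosses the
    rectification kink for some regulator, the column is flagged and a
    one-sided difference consistent with the unperturbed branch is used.
    """
    a = np.asarray(a, dtype=float)
    D = np.asarray(D, dtype=float)
    nx = geometry.nx
    _, base_branch = _production_rate_of_change(a, D, geometry, params)
    R = np.empty((nx, nx))
    flagged = False
    for j in range(nx):
        dp = np.zeros(nx)
        dp[j] = delta
        f_plus, br_plus = _production_rate_of_change(a, D + dp, geometry, params)
        f_minus, br_minus = _production_rate_of_change(a, D - dp, geometry, params)
        if np.array_equal(br_plus, br_minus):
            R[:, j] = (f_plus - f_minus) / (2 * delta)
        else:
            flagged = True
            f0, _ = _production_rate_of_change(a, D, geometry, params)
            if np.array_equal(br_plus, base_branch):
                R[:, j] = (f_plus - f0) / delta
            else:
                R[:, j] = (f0 - f_minus) / delta
    ang, gap = _dominant_direction(0.5 * (R + R.T))
    return ResponsivenessEstimate(matrix=R, method="finite-difference",
                                  learned_angle=ang, eigen_gap=gap,
                                  kink_flagged=flagged)


def _dominant_direction(R: np.ndarray, gap_tol: float = 1e-6):
    w, v = np.linalg.eigh(R)
    gap = float(w[-1] - w[-2]) if w.size > 1 else float(w[-1])
    if R.shape == (2, 2):
        scale = max(abs(np.trace(R)), np.abs(w).max(), 1e-300)
        if gap < gap_tol * scale:
            return float("nan"), gap
        ang = float(np.arctan2(v[1, -1], v[0, -1]) % np.pi)
        return ang, gap
    return float("nan"), gap


def learned_angle(R: np.ndarray, gap_tol: float = 1e-6) -> float:
    """Direction (mod pi) of the dominant eigenvector of a 2x2 responsiveness.

    Returns ``nan`` when the eigenvalue gap is below ``gap_tol * trace``
    (isotropic responsiveness has no learned direction).  Non-symmetric
    input is symmetrized with a warning.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (2, 2):
        raise ValueError("learned_angle expects a 2x2 matrix")
    if not np.allclose(R, R.T, atol=1e-9 * max(1.0, np.abs(R).max())):
        warnings.warn("responsiveness matrix is not symmetric; symmetrizing",
                      stacklevel=2)
    R = 0.5 * (R + R.T)
    ang, _ = _dominant_direction(R, gap_tol)
    return ang


def angle_error(estimate: float, truth: float) -> float:
    """Signed angular difference modulo pi, mapped to (-pi/2, pi/2]."""
    d = (estimate - truth) % np.pi
    if d > np.pi / 2:
        d -= np.pi
    return float(d)


# ---------------------------------------------------------------------------
# minimal fluctuation strength for learning


def gamma_threshold(geometry: RegulatorGeometry, params: LearningParams,
                    env_template: OUParams, kappa: float,
                    bracket: tuple[float, float] = (1e-6, 2.0),
                    duration: float = 1200.0, discard: float = 0.5,
                    seed: int = 0, rel_tol: float = 0.05,
                    max_iter: int = 40) -> float:
    """Minimal Γ at which more than Nx regulators are sustained-active.

    A regulator is sustained when its time-averaged rectified drive
    ``<max(d, sigma . (1 - x))>`` is at least the degradation ``kappa`` (net
    non-negative growth).  The threshold is found by bisection on the
    (Nx+1)-th largest mean drive minus ``kappa``; common random numbers make
    the detector deterministic in Γ.  Scales linearly with ``kappa``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    params = LearningParams(tau_a=params.tau_a, kappa=kappa, d=params.d,
                            x0=params.x0, P0=params.P0,
                            self_activation=params.self_activation,
                            a_floor=params.a_floor)
    # start from the adapted mean-matching state (non-negative least
    # squares) with the surplus regulators at the floor, so the
    # sub-threshold statistics are probed without waiting out the slow
    # decay of unused activities; the mean-matching regulators hover at
    # drive = kappa by stationarity, so activation is judged on the
    # surplus set only
    from scipy.optimize import nnls
    a_match, _ = nnls(geometry.sigma.T, env_template.dbar)
    surplus = a_match <= params.a_floor
    if not surplus.any():
        raise ValueError("geometry has no surplus regulator beyond the "
                         "mean-matching set; no threshold to detect")
    a0 = np.maximum(a_match, params.a_floor)

    def excess_drive(gamma: float) -> float:
        env = OUParams(dbar=env_template.dbar, M=env_template.M,
                       gamma=gamma, dt=env_template.dt)
        demand = simulate_demand(EpochSchedule.single(env, duration), seed)
        circ = simulate_learning(demand, geometry, params, a0=a0)
        n = circ.x.shape[0]
        sl = slice(int(discard * n), n)
        g = geometry.sigma @ (1.0 - circ.x[sl].T)       # (Na, n_kept)
        mean_drive = np.maximum(g, params.d).mean(axis=1)
        return float(mean_drive[surplus].max() - kappa)

    lo, hi = bracket
    f_lo = excess_drive(lo)
    if f_lo >= 0:
        # degradation too weak to ever gate learning (e.g. kappa = 0)
        return lo
    f_hi = excess_drive(hi)
    if f_hi <= 0:
        raise ValueError(
            f"no threshold in bracket ({lo:g}, {hi:g}): excess drive "
            f"{f_lo:g} at lo, {f_hi:g} at hi")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        if excess_drive(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi / lo - 1 < rel_tol:
            break
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# canonical protocols


def _schedule_1d(gammas, epoch_duration: float, dt: float,
                 M: float = 1.0) -> EpochSchedule:
    return EpochSchedule(tuple(
        (OUParams(dbar=np.ones(1), M=np.array([[M]]), gamma=g, dt=dt), epoch_duration)
        for g in gammas))


def _schedule_2d_angles(alphas, gamma: float, lambdas, epoch_duration: float,
                        dt: float) -> EpochSchedule:
    l1, l2 = lambdas
    return EpochSchedule(tuple(
        (OUParams(dbar=np.ones(2), M=build_anisotropy_matrix(a, l1, l2),
                  gamma=gamma, dt=dt), epoch_duration)
        for a in alphas))


def _mean_over_epochs(values: np.ndarray, epoch_index: np.ndarray,
                      discard: float) -> np.ndarray:
    return np.array([values[s].mean(axis=0)
                     for s in _epoch_slices(epoch_index, discard)])


def protocol_variance_epochs(seed: int, gammas=(0.01, 0.05, 0.2),
                             epoch_duration: float = 2000.0, dt: float = 1e-2,
                             params: LearningParams | None = None,
                             discard: float = DEFAULT_DISCARD,
                             burn_in: float = 0.0) -> dict:
    """One-dimensional variance-learning epochs (activator/repressor pair).

    Steps Γ through ``gammas`` with mean demand 1 and unit stiffness, runs
    the learning pair and SEPI on the same demand realization, and reports
    per-epoch time averages of ``a+ - a-`` (mean encoding), ``a+ + a-``
    (responsiveness proxy), performance and CIP.  A positive ``burn_in``
    prepends that much time under the first epoch's conditions (excluded
    from all reported statistics) so epoch 1 starts from an adapted state.
    """
    params = params or LearningParams()
    use_gammas = (gammas[0],) + tuple(gammas) if burn_in > 0 else gammas
    durations = ((burn_in,) + (epoch_duration,) * len(gammas)
                 if burn_in > 0 else (epoch_duration,) * len(gammas))
    schedule = EpochSchedule(tuple(
        (OUParams(dbar=np.ones(1), M=np.array([[1.0]]), gamma=g, dt=dt), T)
        for g, T in zip(use_gammas, durations)))
    demand = simulate_demand(schedule, seed)
    skip = 1 if burn_in > 0 else 0
    geom = make_regulator_geometry(2, nx=1)
    learn = simulate_learning(demand, geom, params)
    sepi = simulate_sepi(demand, params)
    a_ep = _mean_over_epochs(learn.a, demand.epoch_index, discard)[skip:]
    return {
        "gammas": np.asarray(gammas, dtype=float),
        "a_diff": a_ep[:, 0] - a_ep[:, 1],
        "a_sum": a_ep[:, 0] + a_ep[:, 1],
        "perf_learning": performance(learn, demand, discard)[skip:],
        "perf_sepi": performance(sepi, demand, discard)[skip:],
        "cip_learning": control_input_power(learn, discard)[skip:],
        "cip_sepi": control_input_power(sepi, discard)[skip:],
        "sepi_activity": _mean_over_epochs(sepi.a, demand.epoch_index,
                                           discard)[skip:, 0],
        "demand": demand,
        "learning": learn,
        "sepi": sepi,
    }


def protocol_angle_epochs(seed: int,
                          alphas=(0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8,
                                  np.pi / 2),
                          gamma: float = 0.05, lambdas=(10.0, 1.0),
                          na: int = 5, epoch_duration: float = 2000.0,
                          dt: float = 5e-3,
                          params: LearningParams | None = None,
                          discard: float = DEFAULT_DISCARD,
                          burn_in: float = 0.0) -> dict:
    """Two-dimensional angle-learning epochs.

    Rotates the dominant-fluctuation direction through ``alphas`` (fixed
    anisotropy), simulates the ``na``-regulator circuit, and reports the
    per-epoch learned angle (dominant eigenvector of the time-averaged
    analytic responsiveness) against the input angle.  ``burn_in`` prepends
    (and excludes) extra time under the first epoch's conditions.
    """
    params = params or LearningParams()
    use_alphas = (alphas[0],) + tuple(alphas) if burn_in > 0 else alphas
    l1, l2 = lambdas
    durations = ((burn_in,) + (epoch_duration,) * len(alphas)
                 if burn_in > 0 else (epoch_duration,) * len(alphas))
    schedule = EpochSchedule(tuple(
        (OUParams(dbar=np.ones(2), M=build_anisotropy_matrix(a, l1, l2),
                  gamma=gamma, dt=dt), T)
        for a, T in zip(use_alphas, durations)))
    demand = simulate_demand(schedule, seed)
    skip = 1 if burn_in > 0 else 0
    geom = make_regulator_geometry(na, nx=2)
    learn = simulate_learning(demand, geom, params)
    a_ep = _mean_over_epochs(learn.a, demand.epoch_index, discard)[skip:]
    angles = np.array([learned_angle(responsiveness_analytic(a, geom, params))
                       for a in a_ep])
    errors = np.array([angle_error(est, al)
                       for est, al in zip(angles, alphas)])
    return {
        "alphas": np.asarray(alphas, dtype=float),
        "learned_angles": angles,
        "angle_errors": errors,
        "activities": a_ep,
        "perf_learning": performance(learn, demand, discard)[skip:],
        "demand": demand,
        "learning": learn,
        "geometry": geom,
    }


def protocol_angle_recovery(seed: int,
                            alphas=(0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8,
                                    np.pi / 2),
                            gamma: float = 0.1, lambdas=(10.0, 1.0),
                            na: int = 5, duration: float = 4000.0,
                            dt: float = 5e-3,
                            params: LearningParams | None = None,
                            discard: float = 0.7) -> dict:
    """Learned-angle recovery with independent adaptation per input angle.

    Each α is simulated as its own stationary environment from the common
    uniform initial state, avoiding the hysteresis of sequential epochs
    (surplus regulators unlearn only at the slow degradation rate).  The
    learned angle is taken from the time-averaged activities over the final
    ``1 - discard`` fraction of the run.
    """
    params = params or LearningParams(kappa=0.03)
    l1, l2 = lambdas
    geom = make_regulator_geometry(na, nx=2)
    angles, errors = [], []
    for k, alpha in enumerate(alphas):
        env = OUParams(dbar=np.ones(2),
                       M=build_anisotropy_matrix(float(alpha), l1, l2),
                       gamma=gamma, dt=dt)
        demand = simulate_demand(EpochSchedule.single(env, duration),
                                 seed + 1000 * k)
        circ = simulate_learning(demand, geom, params)
        abar = circ.a[int(discard * circ.a.shape[0]):].mean(axis=0)
        ang = learned_angle(responsiveness_analytic(abar, geom, params))
        angles.append(ang)
        errors.append(angle_error(ang, float(alpha)))
    return {
        "alphas": np.asarray(alphas, dtype=float),
        "learned_angles": np.asarray(angles),
        "angle_errors": np.asarray(errors),
        "geometry": geom,
    }


def protocol_gamma_sweep(seed: int, gammas=None, na: int = 5,
                         alpha: float = np.pi / 4, lambdas=(10.0, 1.0),
                         duration: float = 1500.0, dt: float = 5e-3,
                         params: LearningParams | None = None,
                         discard: float = DEFAULT_DISCARD,
                         include_ceiling: bool = True) -> pd.DataFrame:
    """Performance vs fluctuation strength for learning circuit and SEPI.

    Each Γ is simulated as an independent stationary environment (common
    random numbers across circuit variants).  Optionally attaches the
    matched-CIP optimal ceiling for each circuit.
    """
    if gammas is None:
        gammas = np.logspace(-3, 0, 7)
    params = params or LearningParams(kappa=0.05)
    l1, l2 = lambdas
    M = build_anisotropy_matrix(alpha, l1, l2)
    geom = make_regulator_geometry(na, nx=2)
    rows = []
    for k, g in enumerate(gammas):
        env = OUParams(dbar=np.ones(2), M=M, gamma=float(g), dt=dt)
        demand = simulate_demand(EpochSchedule.single(env, duration),
                                 seed + 1000 * k)
        learn = simulate_learning(demand, geom, params)
        sepi = simulate_sepi(demand, params)
        row = {
            "gamma": float(g),
            "perf_learning": performance(learn, demand, discard)[0],
            "perf_sepi": performance(sepi, demand, discard)[0],
            "cip_learning": control_input_power(learn, discard)[0],
            "cip_sepi": control_input_power(sepi, discard)[0],
        }
        if include_ceiling:
            row["ceiling_at_learning_cip"] = oc.ceiling_at_cip(
                env, row["cip_learning"])
            row["ceiling_at_sepi_cip"] = oc.ceiling_at_cip(env, row["cip_sepi"])
        rows.append(row)
    return pd.DataFrame(rows)


def _equal_variance_lambdas(ratio: float, reference=(10.0, 1.0)):
    """Eigenvalue pair with given ratio keeping tr(M^-1) as in ``reference``."""
    c0 = 1.0 / reference[0] + 1.0 / reference[1]
    l2 = (1.0 + 1.0 / ratio) / c0
    return ratio * l2, l2


def protocol_anisotropy_sweep(seed: int, ratios=(1.0, 2.0, 5.0, 10.0, 20.0),
                              gamma: float = 0.05, alpha: float = np.pi / 4,
                              duration: float = 1500.0, dt: float = 5e-3,
                              params: LearningParams | None = None,
                              discard: float = DEFAULT_DISCARD) -> pd.DataFrame:
    """Performance vs correlation strength at fixed total demand variance.

    The eigenvalue ratio of ``M`` is swept while ``trace(M^{-1})`` (hence
    the summed demand variance) is held at its reference value; with the
    soft axis at 45 degrees this varies the correlation between the two
    demands.  Compares Na=5, the Na=4 two-independent-pairs arrangement, and
    SEPI on common noise.
    """
    params = params or LearningParams(kappa=0.03)
    geom5 = make_regulator_geometry(5, nx=2)
    geom4 = make_regulator_geometry(4, nx=2)     # {0, 90, 180, 270} degrees
    rows = []
    for k, r in enumerate(ratios):
        l1, l2 = _equal_variance_lambdas(float(r))
        env = OUParams(dbar=np.ones(2),
                       M=build_anisotropy_matrix(alpha, l1, l2),
                       gamma=gamma, dt=dt)
        demand = simulate_demand(EpochSchedule.single(env, duration),
                                 seed + 1000 * k)
        rows.append({
            "ratio": float(r),
            "correlation": float((1 / l2 - 1 / l1) / (1 / l2 + 1 / l1)),
            "perf_na5": performance(simulate_learning(demand, geom5, params),
                                    demand, discard)[0],
            "perf_na4": performance(simulate_learning(demand, geom4, params),
                                    demand, discard)[0],
            "perf_sepi": performance(simulate_sepi(demand, params),
                                     demand, discard)[0],
        })
    return pd.DataFrame(rows)


def protocol_ablation_grid(seed: int, na_list=(1, 2, 3, 4, 5),
                           d_list=(0.0, -0.3, -10.0),
                           self_activation: bool = True,
                           alphas=ABLATION_ALPHAS, gamma: float = 0.05,
                           lambdas=(10.0, 1.0), duration: float = 1000.0,
                           dt: float = 5e-3,
                           base_params: LearningParams | None = None,
                           discard: float = DEFAULT_DISCARD) -> pd.DataFrame:
    """Performance gain over SEPI on an (Na, d) grid, averaged over angles.

    Gain is the paired difference (common demand realization) between the
    learning-architecture performance and SEPI's, averaged over the five
    input angles.  The Na=2 row uses the SEPI-like arrangement (regulators
    at 0 and 90 degrees); Na=1 is the single co-activating regulator at 45
    degrees.
    """
    base = base_params or LearningParams(kappa=0.03)
    l1, l2 = lambdas
    rows = []
    for k, alpha in enumerate(alphas):
        env = OUParams(dbar=np.ones(2),
                       M=build_anisotropy_matrix(float(alpha), l1, l2),
                       gamma=gamma, dt=dt)
        demand = simulate_demand(EpochSchedule.single(env, duration),
                                 seed + 1000 * k)
        perf_sepi = performance(simulate_sepi(demand, base), demand, discard)[0]
        for na in na_list:
            if na == 1:
                geom = make_regulator_geometry(1, nx=2, angles=[np.pi / 4])
            elif na == 2:
                geom = make_regulator_geometry(2, nx=2,
                                               angles=[0.0, np.pi / 2])
            else:
                geom = make_regulator_geometry(na, nx=2)
            for d in d_list:
                p = LearningParams(tau_a=base.tau_a, kappa=base.kappa,
                                   d=float(d), x0=base.x0, P0=base.P0,
                                   self_activation=self_activation,
                                   a_floor=base.a_floor)
                perf = performance(simulate_learning(demand, geom, p),
                                   demand, discard)[0]
                rows.append({"alpha": float(alpha), "na": int(na),
                             "d": float(d), "perf": perf,
                             "perf_sepi": perf_sepi,
                             "gain": perf - perf_sepi})
    df = pd.DataFrame(rows)
    out = (df.groupby(["na", "d"], as_index=False)
             .agg(gain=("gain", "mean"), perf=("perf", "mean"),
                  perf_sepi=("perf_sepi", "mean")))
    out["self_activation"] = self_activation
    return out


def protocol_biochem_epochs(seed: int, circuit: str = "allosteric",
                            gammas=(0.01, 0.05, 0.2),
                            epoch_duration: float = 2000.0, dt: float = 1e-2,
                            params=None,
                            discard: float = DEFAULT_DISCARD) -> dict:
    """Variance epochs for the biochemical circuits and their analogues.

    Reports per-epoch mean-squared homeostatic error of the learning circuit
    and its non-learning analogue, plus the per-epoch enzyme totals.
    """
    schedule = _schedule_1d(gammas, epoch_duration, dt)
    demand = simulate_demand(schedule, seed)
    if circuit == "allosteric":
        params = params or biochem.AllostericParams()
        learn = biochem.simulate_allosteric(demand, params, learning=True)
        nolearn = biochem.simulate_allosteric(demand, params, learning=False)
    elif circuit == "bifunctional":
        params = params or biochem.BifunctionalParams()
        learn = biochem.simulate_bifunctional(demand, params, learning=True)
        nolearn = biochem.simulate_bifunctional(demand, params, learning=False)
    else:
        raise ValueError(f"unknown circuit {circuit!r}")
    a_ep = _mean_over_epochs(learn.a, demand.epoch_index, discard)
    return {
        "gammas": np.asarray(gammas, dtype=float),
        "mse_learning": homeostatic_error(learn, discard=discard),
        "mse_analogue": homeostatic_error(nolearn, discard=discard),
        "enzyme_total": a_ep.sum(axis=1),
        "demand": demand,
        "learning": learn,
        "analogue": nolearn,
    }


_PROTOCOLS = {
    "variance-epochs": protocol_variance_epochs,
    "angle-epochs": protocol_angle_epochs,
    "angle-recovery": protocol_angle_recovery,
    "gamma-sweep": protocol_gamma_sweep,
    "anisotropy-sweep": protocol_anisotropy_sweep,
    "ablation-grid": protocol_ablation_grid,
    "biochem": protocol_biochem_epochs,
}


def run_sweep(spec: dict):
    """Dispatch a sweep described by a plain dict.

    ``spec`` names the protocol and its keyword arguments, e.g.
    ``{"protocol": "gamma-sweep", "seed": 0, "na": 5}``.
    """
    spec = dict(spec)
    try:
        name = spec.pop("protocol")
        fn = _PROTOCOLS[name]
    except KeyError as err:
        raise ValueError(
            f"sweep spec must name a protocol among {sorted(_PROTOCOLS)}"
        ) from err
    if "seed" not in spec:
        raise ValueError("sweep spec must carry an explicit seed")
    return fn(**spec)
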