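"""Regulatory circuits: simple end-product inhibition and its learning variant.

Two architectures are simulated against a given demand trajectory ``D(t)``.

*Simple end-product inhibition* (SEPI), one regulator per metabolite:

    x = P / D,    P = a,    tau_a * da/dt = 1 - x.

*Learning architecture*: ``Na`` regulators (possibly ``Na > Nx``) with a
constant direction matrix ``sigma`` (rows of unit length), self-activation
and a rectified-linear coupling to the metabolite deviations:

    x_i = P_i / D_i
    P_i = sum_mu sigma[mu, i] * a_mu
    tau_a * da_mu/dt = a_mu * max(d, sum_i sigma[mu, i] (1 - x_i)) - kappa a_mu

Units are chosen so the metabolite set point and the production unit are 1.
Metabolite concentrations are enforced algebraically (``x = P/D``) because
metabolite turnover is fast compared to regulation.  The excess regulators
(``Na > Nx``) are slow degrees of freedom that store the fluctuation
statistics of ``D``; self-activation converts the stored activity into a
faster response, and the rectification ``max(d, .)`` is the nonlinearity that
senses fluctuation magnitude.  Removing the ``a_mu`` prefactor (self
activation off) or sending ``d -> -inf`` recovers a linear, non-learning
system.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import linprog

from .environment import DemandTrajectory

__all__ = [
    "RegulatorGeometry",
    "LearningParams",
    "CircuitTrajectory",
    "make_regulator_geometry",
    "simulate_sepi",
    "simulate_learning",
    "responsiveness_analytic",
    "write_circuit_csv",
    "read_circuit_csv",
]

logger = logging.getLogger(__name__)

#: floor applied to production before the division x = P/D, with logging.
PRODUCTION_FLOOR = 1e-3


@dataclass(frozen=True)
class RegulatorGeometry:
    """Constant regulator direction matrix ``sigma`` (Na x Nx), unit rows.

    For two metabolites each row is a point on the unit circle and is
    summarized by its angle; ``angles`` is populated in that case.
    """

    sigma: np.ndarray
    angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "sigma", sigma)
        if sigma.shape[0] < 1:
            raise ValueError("need at least one regulator")
        norms = np.linalg.norm(sigma, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sigma rows must have unit Euclidean norm")
        if sigma.shape[1] == 2 and self.angles is None:
            object.__setattr__(
                self, "angles", np.arctan2(sigma[:, 1], sigma[:, 0]))
        if not self.positively_spans():
            warnings.warn(
                "regulator directions do not positively span demand space; "
                "mean demand cannot be matched with non-negative activities",
                stacklevel=2)

    @property
    def na(self) -> int:
        return self.sigma.shape[0]

    @property
    def nx(self) -> int:
        return self.sigma.shape[1]

    def positively_spans(self, target: np.ndarray | None = None) -> bool:
        """Whether some ``a >= 0`` solves ``sigma^T a = target`` (default 1)."""
        if target is None:
            target = np.ones(self.nx)
        res = linprog(c=np.zeros(self.na), A_eq=self.sigma.T, b_eq=target,
                      bounds=[(0, None)] * self.na, method="highs")
        return bool(res.success)


@dataclass(frozen=True)
class LearningParams:
    """Parameters of the regulator dynamics.

    tau_a : regulator time scale (time units); default 10, well separated
        from the demand fluctuation time scale ~1/lambda.
    kappa : dimensionless degradation, small compared to the set point.
    d : rectification threshold (<= 0); d=0 is the strong nonlinearity,
        d -> -inf the linear limit.
    x0, P0 : metabolite set point and production unit (both 1 by choice of
        units).
    self_activation : whether the a_mu prefactor multiplies the drive.
    a_floor : smallest allowed activity (keeps multiplicative dynamics
        revivable).
    """

    tau_a: float = 10.0
    kappa: float = 1e-3
    d: float = 0.0
    x0: float = 1.0
    P0: float = 1.0
    self_activation: bool = True
    a_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau_a <= 0:
            raise ValueError("tau_a must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.d > 0:
            raise ValueError("d must be <= 0")
        if self.a_floor <= 0:
            raise ValueError("a_floor must be > 0")


@dataclass(frozen=True)
class CircuitTrajectory:
    """Time-indexed circuit state on the demand grid."""

    times: np.ndarray
    a: np.ndarray          # (n, Na) regulator activities
    P: np.ndarray          # (n, Nx) production
    x: np.ndarray          # (n, Nx) metabolite concentrations
    epoch_index: np.ndarray
    floor_hit_count: int = 0
    p_floor_count: int = 0

    def __post_init__(self) -> None:
        n = self.times.shape[0]
        if not (self.a.shape[0] == self.P.shape[0] == self.x.shape[0] == n
                == self.epoch_index.shape[0]):
            raise ValueError("trajectory arrays must align with the time grid")

    @property
    def na(self) -> int:
        return self.a.shape[1]

    @property
    def nx(self) -> int:
        return self.P.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def make_regulator_geometry(na: int, nx: int = 2,
                            angles=None) -> RegulatorGeometry:
    """Build a regulator geometry.

    Defaults: for ``nx == 2``, ``na`` unit vectors at equally spaced angles
    ``2 pi (mu - 1) / na``; for ``nx == 1`` the activator/repressor pair
    ``(+1), (-1)`` when ``na == 2`` (signs alternate for other ``na``).
    Explicit ``angles`` (radians, ``nx == 2`` only) override the default.
    """
    if na < 1:
        raise ValueError("na must be >= 1")
    if nx == 1:
        if angles is not None:
            raise ValueError("angles only apply to nx=2")
        sigma = np.array([[1.0 if mu % 2 == 0 else -1.0] for mu in range(na)])
        return RegulatorGeometry(sigma=sigma)
    if nx == 2:
        if angles is None:
            theta = 2.0 * np.pi * np.arange(na) / na
        else:
            theta = np.asarray(angles, dtype=float)
            if theta.shape != (na,):
                raise ValueError(f"need {na} angles, got {theta.shape}")
        sigma = np.column_stack([np.cos(theta), np.sin(theta)])
        return RegulatorGeometry(sigma=sigma, angles=theta)
    raise ValueError("nx > 2 is unsupported without an explicit sigma matrix")


@njit(cache=True)
def _sepi_kernel(D, a0, dt, tau_a):  # pragma: no cover - jitted
    n, nx = D.shape
    a = a0.copy()
    a_out = np.empty((n, nx))
    x_out = np.empty((n, nx))
    for t in range(n):
        a_out[t] = a
        for i in range(nx):
            x = a[i] / D[t, i]
            x_out[t, i] = x
            a[i] += dt / tau_a * (1.0 - x)
    return a_out, x_out


@njit(cache=True)
def _learning_kernel(D, sigma, a0, dt, tau_a, kappa, d, a_floor,
                     p_floor, self_act):  # pragma: no cover - jitted
    n, nx = D.shape
    na = sigma.shape[0]
    a = a0.copy()
    a_out = np.empty((n, na))
    P_out = np.empty((n, nx))
    x_out = np.empty((n, nx))
    floor_hits = 0
    p_floor_hits = 0
    one_minus_x = np.empty(nx)
    for t in range(n):
        a_out[t] = a
        record = True
        # stability-preserving sub-steps: the adapted feedback gain can
        # reach sum(a)/(tau_a * min D), far beyond the demand-grid limit
        dmin = D[t, 0]
        for i in range(1, nx):
            if D[t, i] < dmin:
                dmin = D[t, i]
        if self_act:
            atot = 0.0
            for mu in range(na):
                atot += a[mu]
            gain = atot / (tau_a * dmin)
        else:
            gain = na / (tau_a * dmin)
        n_sub = 1 + int(dt * gain / 0.5)
        if n_sub > 10000:
            n_sub = 10000
        dts = dt / n_sub
        for _ in range(n_sub):
            for i in range(nx):
                P = 0.0
                for mu in range(na):
                    P += sigma[mu, i] * a[mu]
                if P < p_floor:
                    P = p_floor
                    if record:
                        p_floor_hits += 1
                x = P / D[t, i]
                if record:
                    P_out[t, i] = P
                    x_out[t, i] = x
                one_minus_x[i] = 1.0 - x
            record = False
            for mu in range(na):
                g = 0.0
                for i in range(nx):
                    g += sigma[mu, i] * one_minus_x[i]
                if g < d:
                    g = d
                if self_act:
                    da = a[mu] * g - kappa * a[mu]
                else:
                    da = g - kappa * a[mu]
                a[mu] += dts / tau_a * da
                if a[mu] < a_floor:
                    a[mu] = a_floor
                    floor_hits += 1
    return a_out, P_out, x_out, floor_hits, p_floor_hits


def simulate_sepi(demand: DemandTrajectory, params: LearningParams,
                  a0: np.ndarray | None = None) -> CircuitTrajectory:
    """Integrate SEPI (one regulator per metabolite) on the demand grid.

    Per metabolite: ``x = a/D`` and ``tau_a da/dt = 1 - x``; the dynamics are
    linear (no degradation, no floor).  ``params.tau_a`` may be chosen freely,
    e.g. to match the responsiveness of a learning circuit.
    """
    if np.any(demand.D <= 0):
        raise ValueError("SEPI requires strictly positive demand")
    nx = demand.nx
    if a0 is None:
        a0 = np.ones(nx)
    a0 = np.asarray(a0, dtype=float)
    if a0.shape != (nx,):
        raise ValueError("a0 must have one entry per metabolite")
    a, x = _sepi_kernel(demand.D, a0, demand.dt, params.tau_a)
    return CircuitTrajectory(times=demand.times, a=a, P=a.copy(), x=x,
                             epoch_index=demand.epoch_index)


def simulate_learning(demand: DemandTrajectory, geometry: RegulatorGeometry,
                      params: LearningParams,
                      a0: np.ndarray | None = None) -> CircuitTrajectory:
    """Integrate the learning architecture on the demand grid.

    Explicit Euler, one regulator update per demand sample.  Activities are
    floored at ``params.a_floor``; production is floored at
    ``PRODUCTION_FLOOR`` before the division ``x = P/D`` (occurrences
    counted and logged).
    """
    if np.any(demand.D <= 0):
        raise ValueError("demand must be strictly positive")
    if geometry.nx != demand.nx:
        raise ValueError("geometry and demand dimensions differ")
    if a0 is None:
        a0 = np.full(geometry.na, 1.0 / geometry.na)
    a0 = np.asarray(a0, dtype=float)
    if a0.shape != (geometry.na,):
        raise ValueError("a0 must have one entry per regulator")
    a, P, x, floor_hits, p_floor_hits = _learning_kernel(
        demand.D, geometry.sigma, a0, demand.dt, params.tau_a, params.kappa,
        params.d, params.a_floor, PRODUCTION_FLOOR, params.self_activation)
    if p_floor_hits:
        logger.warning("production floored at %g on %d grid points",
                       PRODUCTION_FLOOR, p_floor_hits)
    return CircuitTrajectory(times=demand.times, a=a, P=P, x=x,
                             epoch_index=demand.epoch_index,
                             floor_hit_count=int(floor_hits),
                             p_floor_count=int(p_floor_hits))


def write_circuit_csv(circuit: CircuitTrajectory, path,
                      params: LearningParams | None = None):
    """Write a circuit trajectory as CSV with a JSON parameter sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    cols = {"time": circuit.times, "epoch": circuit.epoch_index}
    for mu in range(circuit.na):
        cols[f"a_{mu + 1}"] = circuit.a[:, mu]
    for i in range(circuit.nx):
        cols[f"P_{i + 1}"] = circuit.P[:, i]
    for i in range(circuit.nx):
        cols[f"x_{i + 1}"] = circuit.x[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"floor_hit_count": circuit.floor_hit_count,
            "p_floor_count": circuit.p_floor_count,
            "params": asdict(params) if params is not None else None}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta,
                                                                  indent=1))
    return path


def read_circuit_csv(path) -> CircuitTrajectory:
    """Read back a trajectory written by :func:`write_circuit_csv`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    a_cols = [c for c in df.columns if c.startswith("a_")]
    p_cols = [c for c in df.columns if c.startswith("P_")]
    x_cols = [c for c in df.columns if c.startswith("x_")]
    return CircuitTrajectory(
        times=df["time"].to_numpy(),
        a=df[a_cols].to_numpy(),
        P=df[p_cols].to_numpy(),
        x=df[x_cols].to_numpy(),
        epoch_index=df["epoch"].to_numpy(dtype=np.int64),
        floor_hit_count=int(meta["floor_hit_count"]),
        p_floor_count=int(meta["p_floor_count"]))


def responsiveness_analytic(a: np.ndarray, geometry: RegulatorGeometry,
                            params: LearningParams) -> np.ndarray:
    """Responsiveness matrix ``R_ij = d(dP_i/dt) / dD_j`` at the set point.

    Linearizing the circuit at ``x ≈ 1``, ``D ≈ Dbar`` with the
    rectification on its active branch gives

        R = (1/tau_a) sum_mu a_mu sigma_mu sigma_mu^T

    (self-activation on; without the prefactor the ``a_mu`` weights drop
    out).  The result is symmetric positive semi-definite; its dominant
    eigenvector is the direction the circuit responds to fastest.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (geometry.na,):
        raise ValueError("activity vector does not match geometry")
    s = geometry.sigma
    w = a if params.self_activation else np.ones_like(a)
    R = (s.T * w) @ s / params.tau_a
    return 0.5 * (R + R.T)
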