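"""Optimal tracking of the OU demand under a control-effort budget.

The theoretical performance ceiling for any circuit is the stationary
linear-quadratic tracking problem: with centered state ``z = (D - Dbar,
P - Dbar)``, demand dynamics ``dD = -M (D - Dbar) dt + sqrt(2 Γ) dW`` and a
freely steered production ``dP/dt = u``, minimize

    E[ ||P - D||^2 + rho ||u||^2 ].

The penalty weight ``rho`` prices control effort; sweeping it traces the
family of optimal strategies parameterized by Control Input Power
(CIP = time-average of ``||dP/dt||^2``).  The optimal feedback ``u = -K z``
comes from the algebraic Riccati equation and steers ``P`` toward the
conditional expected future demand — anisotropically when ``M`` is
anisotropic.  Stationary performance and CIP of any linear policy follow
from a Lyapunov equation, which also lets misspecified policies (e.g. one
optimized for a diagonal approximation of ``M``) be scored under the true
environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_are, solve_continuous_lyapunov

from .environment import OUParams, EpochSchedule, simulate_demand

__all__ = [
    "TrackingPolicy",
    "CeilingPoint",
    "optimal_policy",
    "zero_gain_policy",
    "evaluate_policy",
    "simulate_policy",
    "ceiling_at_cip",
    "ceiling_curve",
    "diagonal_misspecified_ceiling_at_cip",
]


@dataclass(frozen=True)
class TrackingPolicy:
    """Linear feedback ``dP/dt = -K (D - Dbar, P - Dbar)``."""

    rho: float
    gain: np.ndarray          # (Nx, 2 Nx)
    env: OUParams

    @property
    def nx(self) -> int:
        return self.env.nx

    def closed_loop_matrix(self, true_env: OUParams | None = None) -> np.ndarray:
        env = self.env if true_env is None else true_env
        nx = env.nx
        A = np.zeros((2 * nx, 2 * nx))
        A[:nx, :nx] = -env.M
        A[nx:, :] -= self.gain
        return A


@dataclass(frozen=True)
class CeilingPoint:
    """A point on the effort/performance frontier."""

    cip: float
    performance: float


def _lq_matrices(env: OUParams, rho: float):
    nx = env.nx
    A = np.zeros((2 * nx, 2 * nx))
    A[:nx, :nx] = -env.M
    B = np.zeros((2 * nx, nx))
    B[nx:, :] = np.eye(nx)
    I = np.eye(nx)
    Q = np.block([[I, -I], [-I, I]])
    R = rho * np.eye(nx)
    return A, B, Q, R


def optimal_policy(env: OUParams, rho: float) -> TrackingPolicy:
    """Solve the stationary LQ tracking problem for penalty weight ``rho``.

    Returns the stabilizing feedback gain from the algebraic Riccati
    equation.  ``rho -> 0`` approaches perfect tracking (diverging CIP);
    ``rho -> inf`` freezes P at the mean demand.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    A, B, Q, R = _lq_matrices(env, rho)
    try:
        X = solve_continuous_are(A, B, Q, R)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ArithmeticError(
            f"Riccati solve failed for rho={rho:g}, M eigenvalues "
            f"{np.linalg.eigvalsh(env.M)}: {err}") from err
    K = B.T @ X / rho
    policy = TrackingPolicy(rho=float(rho), gain=K, env=env)
    eig = np.linalg.eigvals(policy.closed_loop_matrix())
    if eig.real.max() >= 0:
        raise ArithmeticError(
            f"Riccati solution not stabilizing (max Re eig = {eig.real.max():g})")
    return policy


def zero_gain_policy(env: OUParams) -> TrackingPolicy:
    """The no-control limit: P frozen at the mean demand."""
    nx = env.nx
    return TrackingPolicy(rho=np.inf, gain=np.zeros((nx, 2 * nx)), env=env)


def evaluate_policy(policy: TrackingPolicy,
                    true_env: OUParams | None = None) -> CeilingPoint:
    """Stationary performance and CIP of a policy under ``true_env``.

    Solves the closed-loop Lyapunov equation for the stationary covariance;
    ``true_env`` may differ from the environment the policy was optimized
    for (misspecified evaluation).  Performance is the negated stationary
    tracking error ``-E||P - D||^2``; CIP is ``E||u||^2``.
    """
    env = policy.env if true_env is None else true_env
    if env.nx != policy.nx:
        raise ValueError("environment and policy dimensions differ")
    nx = env.nx
    K = policy.gain
    if not K.any():
        # P pinned at Dbar: tracking error is the stationary OU variance
        _, cov = env.dbar, env.gamma * np.linalg.inv(env.M)
        return CeilingPoint(cip=0.0, performance=-float(np.trace(cov)))
    Acl = np.zeros((2 * nx, 2 * nx))
    Acl[:nx, :nx] = -env.M
    Acl[nx:, :] = -K
    eig = np.linalg.eigvals(Acl)
    if eig.real.max() >= 0:
        raise ArithmeticError(
            f"closed loop unstable under true environment "
            f"(max Re eig = {eig.real.max():g})")
    W = np.zeros((2 * nx, 2 * nx))
    W[:nx, :nx] = 2.0 * env.gamma * np.eye(nx)
    S = solve_continuous_lyapunov(Acl, -W)
    I = np.eye(nx)
    Q = np.block([[I, -I], [-I, I]])
    perf = -float(np.trace(Q @ S))
    cip = float(np.trace(K @ S @ K.T))
    return CeilingPoint(cip=cip, performance=perf)


from numba import njit


@njit(cache=True)
def _policy_loop(D, dbar, K, dt):  # pragma: no cover - jitted
    n, nx = D.shape
    P = dbar.copy()
    err2 = np.empty(n)
    u2 = np.empty(n)
    z = np.empty(2 * nx)
    for t in range(n):
        for i in range(nx):
            z[i] = D[t, i] - dbar[i]
            z[nx + i] = P[i] - dbar[i]
        e2 = 0.0
        s2 = 0.0
        for i in range(nx):
            u_i = 0.0
            for j in range(2 * nx):
                u_i -= K[i, j] * z[j]
            d_i = P[i] - D[t, i]
            e2 += d_i * d_i
            s2 += u_i * u_i
            P[i] += u_i * dt
        err2[t] = e2
        u2[t] = s2
    return err2, u2


def simulate_policy(policy: TrackingPolicy, true_env: OUParams,
                    duration: float, seed: int,
                    discard: float = 0.2) -> CeilingPoint:
    """Monte-Carlo cross-check of :func:`evaluate_policy`.

    Integrates the closed loop on the OU grid and measures time-averaged
    tracking error and control power over the retained part.
    """
    traj = simulate_demand(EpochSchedule.single(true_env, duration), seed)
    err2, u2 = _policy_loop(traj.D, true_env.dbar, policy.gain, traj.dt)
    i0 = int(discard * err2.size)
    return CeilingPoint(cip=float(u2[i0:].mean()),
                        performance=-float(err2[i0:].mean()))


def ceiling_curve(env: OUParams, rhos: np.ndarray | None = None
                  ) -> list[tuple[float, float, float]]:
    """Sweep rho and return ``(rho, cip, performance)`` sorted by CIP."""
    if rhos is None:
        rhos = np.logspace(-7, 7, 57)
    pts = []
    for rho in rhos:
        pol = optimal_policy(env, rho)
        pt = evaluate_policy(pol)
        pts.append((float(rho), pt.cip, pt.performance))
    pts.sort(key=lambda r: r[1])
    return pts


def _interp_at_cip(points: list[tuple[float, float, float]],
                   target_cip: float) -> float:
    cips = np.array([p[1] for p in points])
    perfs = np.array([p[2] for p in points])
    keep = cips > 0
    cips, perfs = cips[keep], perfs[keep]
    if target_cip > cips.max():
        raise ValueError(
            f"target CIP {target_cip:g} beyond swept range (max {cips.max():g}); "
            "extend the rho sweep")
    return float(np.interp(np.log(target_cip), np.log(cips), perfs))


def ceiling_at_cip(env: OUParams, target_cip: float,
                   rhos: np.ndarray | None = None) -> float:
    """Optimal performance attainable at a given Control Input Power.

    Interpolates the rho-swept frontier at ``target_cip`` (log-CIP
    interpolation).  Non-decreasing in ``target_cip``; at zero effort it
    equals ``-trace(Γ M^{-1})``.
    """
    if target_cip < 0:
        raise ValueError("target_cip must be >= 0")
    if target_cip == 0:
        return evaluate_policy(zero_gain_policy(env)).performance
    return _interp_at_cip(ceiling_curve(env, rhos), target_cip)


def diagonal_misspecified_ceiling_at_cip(env: OUParams, target_cip: float,
                                         rhos: np.ndarray | None = None
                                         ) -> float:
    """Best performance of policies that assume independent demand axes.

    Policies are optimized for the environment with the off-diagonal
    entries of ``M`` zeroed, then scored under the true ``env``; the CIP is
    the one realized under the true environment.
    """
    env_diag = OUParams(dbar=env.dbar, M=np.diag(np.diag(env.M)),
                        gamma=env.gamma, dt=env.dt)
    if rhos is None:
        rhos = np.logspace(-7, 7, 57)
    pts = []
    for rho in rhos:
        pol = optimal_policy(env_diag, rho)
        pt = evaluate_policy(pol, true_env=env)
        pts.append((float(rho), pt.cip, pt.performance))
    pts.sort(key=lambda r: r[1])
    if target_cip == 0:
        return evaluate_policy(zero_gain_policy(env)).performance
    return _interp_at_cip(pts, target_cip)
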