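"""Biochemically realistic learning circuits and their non-learning analogues.

Two one-metabolite circuits replace the rectified-linear toy nonlinearity
with Hill kinetics while keeping the three learning ingredients (excess slow
degrees of freedom, nonlinearity, self-activation).

*Allosteric enzyme pair*: two self-activating enzymes, the active form of
E+ synthesizing the metabolite ``x`` and the active form of E- degrading it.
Writing ``a+`` and ``a-`` for the total active concentrations,

    tau_x dx/dt  = gamma_plus a+ - gamma_minus x a- - x D(t)
    tau_a da+/dt = a+ c+^n / (c+^n + x^n) - a+ kappa_plus
    tau_a da-/dt = a- x^m / (c-^m + x^m)  - a- kappa_minus

The non-learning analogue drops the degrading branch ``a-`` entirely; the
remaining buffering of ``x`` (the ``x D`` sink) is set by the environment, so
its homeostatic precision cannot adapt.

*Bifunctional enzyme*: one enzyme catalyzes both synthesis and degradation of
``x``.  The total enzyme ``A`` partitions into an unbound (synthesizing) and
an x-bound (degrading) fraction by a Hill isotherm, and ``A`` itself is
produced at a rate minimized at the set point, so fluctuations of ``x``
upregulate the enzyme:

    a+ = A c^m / (x^m + c^m),        a- = A - a+
    tau_x dx/dt = P0 + gamma_plus a+ - gamma_minus x a- - x D(t)
    tau_A dA/dt = -A kappa + f(x),   f(x) = beta (x - 1)^2 + f0

The non-learning analogue freezes ``A`` at its static-demand steady state
``f0 / kappa``.  In both circuits the task is homeostasis of ``x`` at 1 under
a fluctuating demand, and the buffering strength (hence responsiveness)
scales with the stored enzyme level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .circuits import CircuitTrajectory
from .environment import DemandTrajectory

__all__ = [
    "AllostericParams",
    "BifunctionalParams",
    "simulate_allosteric",
    "simulate_bifunctional",
]

#: sub-steps for the stiff metabolite equation on each regulator step.
_N_SUB = 10
#: ratio tau_x / tau_a below which x is treated in quasi-steady state.
_QSS_RATIO = 1e-2
_X_FLOOR = 1e-9


def _hill_half(c: float, exponent: float) -> float:
    # activation Hill value at x = 1; used to center decay rates on x0 = 1
    return c ** exponent / (c ** exponent + 1.0)


@dataclass(frozen=True)
class AllostericParams:
    """Allosteric enzyme-pair parameters (defaults centred on x0 = 1).

    Decay rates default to the Hill occupancy at the set point, which makes
    ``x = 1`` the static fixed point with a marginal direction along
    simultaneous up/down scaling of (a+, a-) — the circuit's memory.  The
    degrading branch's half-saturation sits above the set point so that both
    branch occupancies are convex at the operating point: fluctuations of
    ``x`` then raise both time-averaged occupancies and upregulate the
    enzyme pair (the variance sensor).
    """

    gamma_plus: float = 2.0
    gamma_minus: float = 1.0
    c_plus: float = 1.0
    c_minus: float = 2.5
    n: float = 2.0
    m: float = 2.0
    kappa_plus: float | None = None
    kappa_minus: float | None = None
    tau_x: float = 0.1
    tau_a: float = 10.0

    def __post_init__(self) -> None:
        if self.kappa_plus is None:
            object.__setattr__(self, "kappa_plus",
                               _hill_half(self.c_plus, self.n))
        if self.kappa_minus is None:
            object.__setattr__(self, "kappa_minus",
                               1.0 - _hill_half(self.c_minus, self.m))
        for name in ("gamma_plus", "gamma_minus", "c_plus", "c_minus",
                     "kappa_plus", "kappa_minus", "tau_x", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n < 1 or self.m < 1:
            raise ValueError("Hill exponents must be >= 1")
        if self.tau_x >= self.tau_a:
            raise ValueError("need timescale separation tau_x < tau_a")


@dataclass(frozen=True)
class BifunctionalParams:
    """Bifunctional-enzyme homeostasis parameters.

    With ``gamma_plus == gamma_minus`` and ``P0 == Dbar`` the static fixed
    point sits at ``x = c = 1`` for any enzyme level; ``f0 = kappa`` puts the
    static enzyme steady state at ``A = 1``.
    """

    P0: float = 1.0
    gamma_plus: float = 1.0
    gamma_minus: float = 1.0
    c: float = 1.0
    m: float = 2.0
    kappa: float = 1e-3
    beta: float = 5.0
    f0: float | None = None
    tau_x: float = 0.1
    tau_A: float = 10.0

    def __post_init__(self) -> None:
        if self.f0 is None:
            object.__setattr__(self, "f0", self.kappa)
        for name in ("P0", "gamma_plus", "gamma_minus", "c", "kappa",
                     "beta", "f0", "tau_x", "tau_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m < 1:
            raise ValueError("Hill exponent must be >= 1")
        if self.tau_x >= self.tau_A:
            raise ValueError("need timescale separation tau_x < tau_A")

    def f(self, x: np.ndarray | float) -> np.ndarray | float:
        """Enzyme production control, minimized at the set point x = 1."""
        return self.beta * (np.asarray(x) - 1.0) ** 2 + self.f0


@njit(cache=True)
def _allosteric_kernel(D, x0, ap0, am0, dt, gp, gm, cp, cm, n, m, kp, km,
                       tau_x, tau_a, n_sub, qss,
                       learning):  # pragma: no cover - jitted
    nt = D.shape[0]
    x = x0
    ap = ap0
    am = am0
    a_out = np.empty((nt, 2))
    P_out = np.empty((nt, 1))
    x_out = np.empty((nt, 1))
    dts = dt / n_sub
    for t in range(nt):
        Dt = D[t, 0]
        if qss:
            x = gp * ap / (gm * am + Dt)
        else:
            for _ in range(n_sub):
                dx = (gp * ap - gm * x * am - x * Dt) / tau_x
                x += dts * dx
                if x < _X_FLOOR:
                    x = _X_FLOOR
        a_out[t, 0] = ap
        a_out[t, 1] = am
        P_out[t, 0] = gp * ap
        x_out[t, 0] = x
        hp = cp ** n / (cp ** n + x ** n)
        ap += dt / tau_a * ap * (hp - kp)
        if learning:
            hm = x ** m / (cm ** m + x ** m)
            am += dt / tau_a * am * (hm - km)
    return a_out, P_out, x_out


@njit(cache=True)
def _bifunctional_kernel(D, x0, A0, dt, P0, gp, gm, c, m, kappa, beta, f0,
                         tau_x, tau_A, n_sub,
                         learning):  # pragma: no cover - jitted
    nt = D.shape[0]
    x = x0
    A = A0
    a_out = np.empty((nt, 2))
    P_out = np.empty((nt, 1))
    x_out = np.empty((nt, 1))
    dts = dt / n_sub
    cm_ = c ** m
    for t in range(nt):
        Dt = D[t, 0]
        for _ in range(n_sub):
            ap = A * cm_ / (x ** m + cm_)
            am = A - ap
            dx = (P0 + gp * ap - gm * x * am - x * Dt) / tau_x
            x += dts * dx
            if x < _X_FLOOR:
                x = _X_FLOOR
        ap = A * cm_ / (x ** m + cm_)
        a_out[t, 0] = ap
        a_out[t, 1] = A - ap
        P_out[t, 0] = P0 + gp * ap
        x_out[t, 0] = x
        if learning:
            A += dt / tau_A * (-A * kappa + beta * (x - 1.0) ** 2 + f0)
    return a_out, P_out, x_out


def _check_demand(demand: DemandTrajectory) -> None:
    if demand.nx != 1:
        raise ValueError("biochemical circuits are one-dimensional")
    if np.any(demand.D <= 0):
        raise ValueError("demand must be strictly positive")


def simulate_allosteric(demand: DemandTrajectory, params: AllostericParams,
                        learning: bool = True,
                        x_init: float = 1.0,
                        a_init: tuple[float, float] | None = None
                        ) -> CircuitTrajectory:
    """Integrate the allosteric enzyme-pair circuit.

    ``learning=False`` drops the degrading branch (``a- = 0``), leaving a
    single end-product-inhibited activator: the non-learning analogue.
    The stiff metabolite equation is solved in quasi-steady state when
    ``tau_x/tau_a < 1e-2``, otherwise by sub-stepped explicit Euler.
    """
    _check_demand(demand)
    if a_init is None:
        # static steady state at x = 1: gp*ap = gm*am + Dbar, split evenly
        am0 = 1.0 if learning else 0.0
        ap0 = (params.gamma_minus * am0 + float(np.mean(demand.D[0]))) \
            / params.gamma_plus
    else:
        ap0, am0 = float(a_init[0]), float(a_init[1])
    if not learning:
        am0 = 0.0
    qss = params.tau_x / params.tau_a < _QSS_RATIO
    a, P, x = _allosteric_kernel(
        demand.D, float(x_init), ap0, am0, demand.dt,
        params.gamma_plus, params.gamma_minus, params.c_plus, params.c_minus,
        params.n, params.m, params.kappa_plus, params.kappa_minus,
        params.tau_x, params.tau_a, _N_SUB, qss, learning)
    return CircuitTrajectory(times=demand.times, a=a, P=P, x=x,
                             epoch_index=demand.epoch_index)


def simulate_bifunctional(demand: DemandTrajectory, params: BifunctionalParams,
                          learning: bool = True,
                          x_init: float = 1.0,
                          A_init: float | None = None) -> CircuitTrajectory:
    """Integrate the bifunctional-enzyme homeostasis circuit.

    The enzyme partitions into synthesizing/degrading fractions by a Hill
    isotherm at every step (so ``a+ + a- == A`` exactly).  ``learning=False``
    freezes the total enzyme at its static-demand steady state ``f0/kappa``.
    """
    _check_demand(demand)
    if A_init is None:
        A_init = params.f0 / params.kappa
    a, P, x = _bifunctional_kernel(
        demand.D, float(x_init), float(A_init), demand.dt,
        params.P0, params.gamma_plus, params.gamma_minus, params.c, params.m,
        params.kappa, params.beta, params.f0, params.tau_x, params.tau_A,
        _N_SUB, learning)
    return CircuitTrajectory(times=demand.times, a=a, P=P, x=x,
                             epoch_index=demand.epoch_index)
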