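"""Mean-field activation dynamics.

Under the mean-field assumption each node sees the global expected
activation fraction instead of its own neighbourhood, and the expected
fraction of active nodes a-hat(t) solves the autonomous ODE

    da/dt = (1 - a) * lambda(a) - a * mu(a),      a(0) = 0.

The deterministic trigger time tau-hat^gamma is the first time a-hat
reaches the threshold gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .rates import RatePair

__all__ = [
    "MeanFieldTrajectory",
    "EquilibriumInfo",
    "solve_activation",
    "equilibrium_fraction",
    "trigger_time",
]

#: integration is stopped once |da/dt| falls below this (saturation)
SATURATION_TOL = 1e-12
#: hard cap on the integration horizon for automatic horizon selection
HORIZON_CAP = 1e6


@dataclass
class MeanFieldTrajectory:
    """Dense-output solution of the activation-fraction ODE.

    ``evaluate(t)`` returns a-hat(t) clipped to [0, 1] for any t in
    [0, t_end]; when the trajectory has saturated (|da/dt| < 1e-12 at
    t_end) evaluation beyond t_end returns the saturated value, which is
    exact up to the saturation tolerance times the extrapolation length.
    """

    rates: RatePair
    t_end: float
    saturated: bool
    solver_meta: dict[str, Any] = field(default_factory=dict)
    _sol: Any = field(default=None, repr=False)
    _t_grid: np.ndarray = field(default=None, repr=False)

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        if np.any(tq < 0):
            raise ValueError("time must be nonnegative")
        over = tq > self.t_end * (1 + 1e-12)
        if np.any(over) and not self.saturated:
            raise ValueError(
                f"trajectory solved only up to t_end={self.t_end}; extend t_end"
            )
        a = self._sol(np.minimum(tq, self.t_end))
        a = np.clip(np.asarray(a, float).reshape(tq.shape), 0.0, 1.0)
        return float(a[0]) if scalar else a

    def derivative(self, t) -> float:
        """Right-hand side (1-a)lambda(a) - a mu(a) at a-hat(t)."""
        a = self.evaluate(t)
        return float((1.0 - a) * self.rates.lambda_fn(a) - a * self.rates.mu_fn(a))

    @property
    def supremum(self) -> float:
        """Largest activation fraction attained on [0, t_end]."""
        return float(np.max(np.clip(self._sol(self._t_grid), 0.0, 1.0)))


@dataclass(frozen=True)
class EquilibriumInfo:
    """An equilibrium activation fraction a* with its residual."""

    a_star: float
    residual: float


def _rhs_factory(rp: RatePair):
    lam, mu = rp.lambda_fn, rp.mu_fn

    def rhs(t, y):
        a = min(max(y[0], 0.0), 1.0)
        return [(1.0 - a) * lam(a) - a * mu(a)]

    return rhs


def solve_activation(
    rp: RatePair,
    t_end: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> MeanFieldTrajectory:
    """Solve the mean-field ODE for the activation fraction.

    Parameters
    ----------
    rp
        Rate pair; both functions must be finite on [0, 1].
    t_end
        Integration horizon.  ``None`` selects the horizon automatically:
        integration proceeds (up to a cap of 1e6 time units) until the
        derivative magnitude drops below the saturation tolerance 1e-12,
        which for every built-in family happens after the trajectory has
        levelled off at its equilibrium.
    rtol, atol
        Local error tolerances of the adaptive Runge-Kutta integrator.
        The tight defaults keep downstream hitting-time integrals accurate
        to well below the 2-decimal reporting precision.
    """
    rhs = _rhs_factory(rp)
    auto = t_end is None
    horizon = HORIZON_CAP if auto else float(t_end)
    if horizon <= 0:
        raise ValueError("t_end must be positive")

    lam, mu = rp.lambda_fn, rp.mu_fn

    def sat_threshold(a: float) -> float:
        # the solver cannot resolve a-hat closer to equilibrium than its
        # own error floor, so the derivative bottoms out near
        # (lambda + mu) * atol; saturation must be declared relative to it
        return max(SATURATION_TOL, 100.0 * atol * (float(lam(a)) + float(mu(a))))

    events = None
    if auto:
        def saturation(t, y):
            a = min(max(y[0], 0.0), 1.0)
            return abs(rhs(t, y)[0]) - sat_threshold(a)

        saturation.terminal = True
        saturation.direction = -1
        events = [saturation]

    res = solve_ivp(
        rhs,
        (0.0, horizon),
        [0.0],
        method="DOP853",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        events=events,
    )
    if not res.success:
        raise RuntimeError(
            f"mean-field integration failed at t={res.t[-1]:.6g}: {res.message}"
        )
    reached = float(res.t[-1])
    a_end = float(res.sol(reached)[0])
    event_fired = auto and res.t_events[0].size > 0
    saturated = event_fired or (
        abs(rhs(reached, [a_end])[0]) <= sat_threshold(a_end) * 1.01
    )
    traj = MeanFieldTrajectory(
        rates=rp,
        t_end=reached,
        saturated=saturated,
        solver_meta={
            "rtol": rtol,
            "atol": atol,
            "n_steps": int(res.t.size),
            "nfev": int(res.nfev),
            "method": "DOP853",
        },
        _sol=lambda t, s=res.sol: np.asarray(s(t))[0],
        _t_grid=res.t,
    )
    return traj


def equilibrium_fraction(rp: RatePair, n_scan: int = 1001) -> EquilibriumInfo:
    """Locate the smallest equilibrium of the activation ODE in [0, 1].

    The right-hand side f(a) = (1-a)lambda(a) - a mu(a) is scanned on a
    uniform grid; the first sign change is refined by Brent's method.
    """
    lam, mu = rp.lambda_fn, rp.mu_fn

    def f(a):
        return float((1.0 - a) * lam(a) - a * mu(a))

    grid = np.linspace(0.0, 1.0, n_scan)
    vals = np.array([f(a) for a in grid])
    root = None
    exact = np.flatnonzero(np.abs(vals) <= 1e-14)
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            root = grid[i]
            break
        if vals[i] * vals[i + 1] < 0:
            root = brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15)
            break
    if root is None and vals[-1] == 0.0:
        root = grid[-1]
    if root is None and exact.size:
        root = grid[exact[0]]
    if root is None:
        raise ValueError("no equilibrium located in [0, 1]")
    return EquilibriumInfo(a_star=float(root), residual=f(float(root)))


def trigger_time(traj: MeanFieldTrajectory, gamma: float) -> float | None:
    """First time the mean-field activation fraction reaches gamma.

    Returns ``None`` when the trajectory saturates strictly below gamma
    (the network never triggers under the mean-field dynamics).  Raises if
    the trajectory is too short to decide either way.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    ts = traj._t_grid
    vals = np.clip(traj._sol(ts), 0.0, 1.0) - gamma
    above = np.flatnonzero(vals >= 0.0)
    if above.size == 0:
        if traj.saturated:
            return None
        raise RuntimeError(
            "trajectory neither crosses gamma nor saturates; extend t_end"
        )
    i = above[0]
    if i == 0:
        return 0.0
    lo, hi = float(ts[i - 1]), float(ts[i])

    def g(t):
        return float(traj.evaluate(t)) - gamma

    return float(brentq(g, lo, hi, xtol=1e-8))
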