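"""Stochastic ground truth for the mean-field and homogeneity layers.

Two exact samplers:

* :func:`simulate_network` runs the full n-node continuous-time chain on
  a graph.  Each passive node i flips at rate lambda(a_i), each active
  node at rate mu(a_i), where a_i is the fraction of i's neighbours that
  are active.  Between events all rates are constant, so the next event
  is drawn by competing exponentials; only the flipped node and its
  neighbours need rate updates.  No time discretisation is involved.

* :func:`simulate_aggregated` samples the time-inhomogeneous (k+1)-state
  key-node chain with up-rates (k-i) lambda(a-hat(t)) and down-rates
  i mu(a-hat(t)) by Lewis-Shedler thinning, using monotone endpoint
  bounds of the rates over short lookahead windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meanfield import MeanFieldTrajectory
from .network import Graph
from .rates import RatePair

__all__ = [
    "SimulationRun",
    "EstimateSummary",
    "simulate_network",
    "simulate_aggregated",
    "summarize",
]


@dataclass
class SimulationRun:
    """One stochastic realisation of the network chain."""

    seed: int
    event_times: np.ndarray = field(repr=False)
    a_path: np.ndarray = field(repr=False)  # active fraction after each event
    tau_gamma: float | None
    tau_k: float | None
    horizon: float
    frozen: bool = False


@dataclass(frozen=True)
class EstimateSummary:
    """Mean and standard error of uncensored hitting-time samples."""

    mean: float
    std_error: float
    n_replicates: int
    n_censored: int


def simulate_network(
    g: Graph,
    rp: RatePair,
    gamma: float,
    horizon: float,
    seed: int,
    stop_when_hit: bool = False,
) -> SimulationRun:
    """Exact event-driven simulation of the n-node chain on a graph.

    All nodes start passive.  Records the active-fraction path and the
    first times tau^gamma (fraction >= gamma) and tau_k (all key nodes
    active); hitting times not reached by the horizon are None
    (censored).  With ``stop_when_hit`` the run ends as soon as both
    hitting times are recorded.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    nxg = g.nx_graph
    n = g.n
    degs = np.array([nxg.degree[i] for i in range(n)], dtype=float)
    if np.any(degs == 0):
        raise ValueError("every node needs at least one neighbour")
    nbrs = [np.fromiter(nxg.neighbors(i), dtype=np.int64) for i in range(n)]
    key = np.array(g.key_nodes, dtype=np.int64)

    rng = np.random.default_rng(seed)
    active = np.zeros(n, dtype=bool)
    act_nbr = np.zeros(n, dtype=float)  # number of active neighbours
    lam, mu = rp.lambda_fn, rp.mu_fn

    def node_rates(idx):
        frac = act_nbr[idx] / degs[idx]
        return np.where(active[idx], np.asarray(mu(frac), float),
                        np.asarray(lam(frac), float))

    rates = np.asarray(node_rates(np.arange(n)), dtype=float)

    t = 0.0
    times: list[float] = []
    a_path: list[float] = []
    n_active = 0
    tau_gamma = None
    tau_k = None
    frozen = False
    n_key_active = 0 if len(key) else None

    while t < horizon:
        total = float(rates.sum())
        if total <= 0:
            frozen = tau_gamma is None
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        i = int(np.searchsorted(np.cumsum(rates), rng.uniform(0.0, total)))
        i = min(i, n - 1)
        flip_to = not active[i]
        active[i] = flip_to
        n_active += 1 if flip_to else -1
        act_nbr[nbrs[i]] += 1.0 if flip_to else -1.0
        upd = np.append(nbrs[i], i)
        rates[upd] = node_rates(upd)
        times.append(t)
        a_path.append(n_active / n)
        if tau_gamma is None and n_active / n >= gamma:
            tau_gamma = t
        if n_key_active is not None:
            if i in key:
                n_key_active += 1 if flip_to else -1
            if tau_k is None and len(key) and n_key_active == len(key):
                tau_k = t
        if stop_when_hit and tau_gamma is not None and (tau_k is not None or not len(key)):
            break

    return SimulationRun(
        seed=seed,
        event_times=np.asarray(times),
        a_path=np.asarray(a_path),
        tau_gamma=tau_gamma,
        tau_k=tau_k,
        horizon=horizon,
        frozen=frozen,
    )


def _interp_rates(rp: RatePair, traj: MeanFieldTrajectory, horizon: float,
                  n_grid: int = 8001):
    """Linear interpolants of lambda(a-hat(t)) and mu(a-hat(t)).

    Because a-hat is monotone in t and each built-in rate function is
    monotone in a, the grid values are monotone, so the interpolants are
    monotone as well and their supremum over any window sits at a window
    endpoint -- exactly the property the thinning bound needs.
    """
    key = (id(rp), id(traj), horizon, n_grid)
    cached = _interp_cache.get(key)
    if cached is not None:
        return cached[0]

    ts = np.linspace(0.0, min(horizon, traj.t_end), n_grid)
    a_vals = traj.evaluate(ts)
    lam_vals = np.asarray(rp.lambda_fn(a_vals), float)
    mu_vals = np.asarray(rp.mu_fn(a_vals), float)

    def lam_of(t: float) -> float:
        return float(np.interp(t, ts, lam_vals))

    def mu_of(t: float) -> float:
        return float(np.interp(t, ts, mu_vals))

    if len(_interp_cache) > 32:
        _interp_cache.clear()
    _interp_cache[key] = ((lam_of, mu_of), rp, traj)
    return lam_of, mu_of


#: replicate loops reuse the same (rp, traj, horizon); keep the grids warm
_interp_cache: dict = {}


def simulate_aggregated(
    rp: RatePair,
    k: int,
    traj: MeanFieldTrajectory,
    seed: int,
    horizon: float,
) -> float | None:
    """Sample the absorption time of the aggregated key-node chain.

    Thinning: over a lookahead window the total jump rate out of the
    current state is bounded by its values at the window endpoints (valid
    because a-hat is monotone and every built-in rate function is
    monotone in a); proposals at the bound rate are accepted with
    probability instantaneous/bound.  A violated bound halves the window;
    persistent violation raises.  Returns the first entry time into the
    all-active state, or None if not absorbed by the horizon.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if traj.t_end < horizon and not traj.saturated:
        raise ValueError("trajectory does not cover the horizon")
    rng = np.random.default_rng(seed)
    lam_of, mu_of = _interp_rates(rp, traj, float(horizon))

    grid = np.linspace(0.0, 1.0, 256)
    sup_rate = float(np.max(rp.lambda_fn(grid))) + float(np.max(rp.mu_fn(grid)))
    base_window = 1.0 / (k * sup_rate) if sup_rate > 0 else horizon

    state = 0
    t = 0.0
    window = base_window
    min_window = base_window / 2**20
    while t < horizon:
        w = min(window, horizon - t)
        # per-component endpoint bound: each rate is monotone in time
        bound = (
            (k - state) * max(lam_of(t), lam_of(t + w))
            + state * max(mu_of(t), mu_of(t + w))
        ) * (1.0 + 1e-12)
        if bound <= 0.0:
            t += w
            continue
        s = t
        accepted = False
        while True:
            s += rng.exponential(1.0 / bound)
            if s >= t + w:
                break
            up = (k - state) * lam_of(s)
            inst = up + state * mu_of(s)
            if inst > bound:
                if window <= min_window:
                    raise RuntimeError(
                        "thinning bound violated persistently; non-monotone "
                        "a-hat segment needs a finer lookahead"
                    )
                window /= 2.0
                accepted = None  # restart window with smaller lookahead
                break
            if rng.uniform() * bound <= inst:
                state += 1 if rng.uniform() * inst <= up else -1
                t = s
                accepted = True
                break
        if accepted is None:
            continue
        if not accepted:
            t += w
            continue
        if state == k:
            return float(t)
    return None


def summarize(samples) -> EstimateSummary:
    """Mean and standard error of hitting-time samples; None = censored."""
    vals = [s for s in samples if s is not None]
    n_cens = sum(1 for s in samples if s is None)
    if len(vals) < 2:
        raise ValueError("need at least two uncensored samples")
    arr = np.asarray(vals, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return EstimateSummary(
        mean=float(arr.mean()),
        std_error=se,
        n_replicates=len(samples),
        n_censored=n_cens,
    )
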