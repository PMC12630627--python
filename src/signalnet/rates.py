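"""Activation/deactivation rate-function pairs.

A signal network's node dynamics are governed by two rate functions of the
global activation fraction ``a`` in [0, 1]:

* ``lambda(a)`` — rate (1/time) at which a passive node becomes active,
* ``mu(a)``     — rate (1/time) at which an active node becomes passive.

Several named families are built in, including the Gompertz-type aging pair
``lambda(a) = Gamma_0 exp(r_plus a)``, ``mu(a) = (Gamma_0 / R) exp(-r_minus a)``
used to model damage accumulation in aging networks.  A ``custom`` family
accepts small arithmetic expressions in the variable ``a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import sympy
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

__all__ = ["RatePair", "make_rates", "check_rate_properties", "BUILTIN_FAMILIES"]

logger = logging.getLogger(__name__)

RateFn = Callable[[np.ndarray | float], np.ndarray | float]


@dataclass(frozen=True)
class RatePair:
    """A pair of rate functions (activation, deactivation).

    Both functions map an activation fraction in [0, 1] to a nonnegative
    rate with units 1/time and are vectorised over numpy arrays.
    Evaluation is pure: the same input always yields the same value.
    """

    family: str
    params: Mapping[str, float]
    lambda_fn: RateFn = field(repr=False)
    mu_fn: RateFn = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))


def _const_fn(c: float) -> RateFn:
    def f(a):
        return np.asarray(a, dtype=float) * 0.0 + c

    return f


def _require(params: Mapping[str, float], names: list[str], family: str,
             positive: tuple[str, ...] = ()) -> dict[str, float]:
    missing = [n for n in names if n not in params]
    if missing:
        raise ValueError(
            f"family '{family}' requires parameters {names}; missing {missing}"
        )
    out = {n: float(params[n]) for n in names}
    for n in names:
        if out[n] < 0:
            raise ValueError(f"parameter '{n}' of family '{family}' must be nonnegative")
    for n in positive:
        if out[n] <= 0:
            raise ValueError(f"parameter '{n}' of family '{family}' must be positive")
    return out


_EXPR_LOCALS = {
    "exp": sympy.exp,
    "log": sympy.log,
    "a": sympy.Symbol("a", real=True),
}


def _parse_rate_expr(expr: str) -> RateFn:
    """Compile a small arithmetic expression in ``a`` (+ - * / ^ exp log)."""
    tree = parse_expr(
        str(expr),
        local_dict=_EXPR_LOCALS,
        transformations=standard_transformations + (convert_xor,),
        evaluate=True,
    )
    extra = tree.free_symbols - {_EXPR_LOCALS["a"]}
    if extra:
        raise ValueError(f"unknown symbols in rate expression: {sorted(map(str, extra))}")
    fn = sympy.lambdify(_EXPR_LOCALS["a"], tree, modules="numpy")

    def f(a):
        return np.asarray(fn(np.asarray(a, dtype=float)), dtype=float) + 0.0 * np.asarray(a, dtype=float)

    return f


BUILTIN_FAMILIES = (
    "constant",
    "exp_decay_const",
    "const_exp_growth",
    "power_const",
    "log_pair",
    "gompertz_aging",
    "custom",
)


def make_rates(family: str, params: Mapping[str, float | str] | None = None) -> RatePair:
    """Construct a :class:`RatePair` from a family name and parameters.

    Families
    --------
    constant
        ``lambda(a) = c_lambda``, ``mu(a) = c_mu``.
    exp_decay_const
        ``lambda(a) = exp(-a)``, ``mu(a) = 1``.
    const_exp_growth
        ``lambda(a) = 1``, ``mu(a) = exp(a)``.
    power_const
        ``lambda(a) = (a + 1)^-1``, ``mu(a) = 1``.
    log_pair
        ``lambda(a) = 1 / log(3 + a)``, ``mu(a) = log(3 + a)``.
    gompertz_aging
        ``lambda(a) = Gamma_0 exp(r_plus a)``,
        ``mu(a) = (Gamma_0 / R) exp(-r_minus a)``.
    custom
        ``params['lambda']`` and ``params['mu']`` are arithmetic
        expressions in the variable ``a`` (operators + - * / ^, functions
        exp and log).
    """
    params = dict(params or {})
    if family == "constant":
        p = _require(params, ["c_lambda", "c_mu"], family)
        return RatePair(family, p, _const_fn(p["c_lambda"]), _const_fn(p["c_mu"]))
    if family == "exp_decay_const":
        return RatePair(family, {}, lambda a: np.exp(-np.asarray(a, float)), _const_fn(1.0))
    if family == "const_exp_growth":
        return RatePair(family, {}, _const_fn(1.0), lambda a: np.exp(np.asarray(a, float)))
    if family == "power_const":
        return RatePair(family, {}, lambda a: 1.0 / (np.asarray(a, float) + 1.0), _const_fn(1.0))
    if family == "log_pair":
        return RatePair(
            family,
            {},
            lambda a: 1.0 / np.log(3.0 + np.asarray(a, float)),
            lambda a: np.log(3.0 + np.asarray(a, float)),
        )
    if family == "gompertz_aging":
        p = _require(params, ["Gamma_0", "r_plus", "r_minus", "R"], family,
                     positive=("Gamma_0", "R"))
        g0, rp_, rm, R = p["Gamma_0"], p["r_plus"], p["r_minus"], p["R"]
        return RatePair(
            family,
            p,
            lambda a: g0 * np.exp(rp_ * np.asarray(a, float)),
            lambda a: (g0 / R) * np.exp(-rm * np.asarray(a, float)),
        )
    if family == "custom":
        for key in ("lambda", "mu"):
            if key not in params:
                raise ValueError(f"family 'custom' requires expressions 'lambda' and 'mu'")
        return RatePair(
            family,
            {k: str(v) for k, v in params.items()},
            _parse_rate_expr(params["lambda"]),
            _parse_rate_expr(params["mu"]),
        )
    raise ValueError(f"unknown rate family '{family}'; known: {BUILTIN_FAMILIES}")


def check_rate_properties(rp: RatePair, grid_size: int = 1001) -> dict[str, bool]:
    """Report whether the pair satisfies the usual qualitative assumptions.

    The modelling assumptions behind the triggering framework are that
    ``lambda`` is non-increasing, ``mu`` is non-decreasing (more active
    neighbours shorten inactivity and lengthen activity) and that
    ``lambda(a) < mu(a)`` on (0, 1] (so the activation fraction saturates
    below 1 rather than growing without bound).  Violations are reported
    and logged as warnings, never raised: the Gompertz aging pair is a
    legitimate model that breaks both patterns.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    lam = np.asarray(rp.lambda_fn(grid), dtype=float)
    mu = np.asarray(rp.mu_fn(grid), dtype=float)
    tol = 1e-12
    report = {
        "lambda_decreasing": bool(np.all(np.diff(lam) <= tol)),
        "mu_increasing": bool(np.all(np.diff(mu) >= -tol)),
        "lambda_below_mu_on_(0,1]": bool(np.all(lam[1:] < mu[1:])),
    }
    for name, ok in report.items():
        if not ok:
            logger.warning("rate pair %s violates '%s' (advisory check)", rp.family, name)
    return report
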