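"""Optimal number of key nodes.

The network is triggered when a fraction gamma of nodes is active; all k
key nodes being active is the monitored proxy.  The optimal key-node
count k_c(gamma) is the k whose expected hitting time E[tau_k] is closest
to the (mean-field) trigger time tau-hat^gamma, made precise via

    k_minus = sup{k : tau-hat^gamma >= E[tau_k]}  (sup of empty set -> 1)
    k_plus  = inf{k : tau-hat^gamma <= E[tau_k]}  (inf of empty set -> k_max)

with ties broken towards k_minus.  Because E[tau_k] is strictly
increasing in k, the ladder of expectations is computed incrementally and
stops at the first k whose expectation exceeds the trigger time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import keynodes, meanfield
from .rates import RatePair

__all__ = ["OptimalKResult", "optimal_key_count"]

#: absolute tolerance on the tie-rule distance comparison
TIE_TOL = 1e-9


@dataclass(frozen=True)
class OptimalKResult:
    """k_c(gamma) together with the expectation ladder that decided it."""

    gamma: float
    trigger: float | None
    ladder: dict[int, float] = field(repr=False)
    k_minus: int
    k_plus: int
    k_c: int
    never_triggers: bool = False


def optimal_key_count(
    rp: RatePair,
    gamma: float = 0.4,
    k_max: int = 10,
    mode: str = "literal",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> OptimalKResult:
    """Compute k_c(gamma) for a rate pair.

    ``k_max`` caps the search (it stands in for the network size n in the
    sup/inf conventions).  If the mean-field trajectory never reaches
    gamma, the result is flagged and k_c = k_max by the inf-of-empty-set
    convention.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    traj = meanfield.solve_activation(rp, rtol=rtol, atol=atol)
    trigger = meanfield.trigger_time(traj, gamma)

    ladder: dict[int, float] = {}
    for k in range(1, k_max + 1):
        dist = keynodes.solve_state_probabilities(
            rp, k, mode=mode, traj=traj, rtol=rtol, atol=atol
        )
        ladder[k] = keynodes.expected_hitting_time(dist).expectation
        if trigger is not None and ladder[k] >= trigger:
            break

    if trigger is None:
        return OptimalKResult(
            gamma=gamma, trigger=None, ladder=ladder,
            k_minus=max(ladder), k_plus=k_max, k_c=k_max, never_triggers=True,
        )

    below = [k for k, e in ladder.items() if trigger >= e]
    above = [k for k, e in ladder.items() if trigger <= e]
    k_minus = max(below) if below else 1
    k_plus = min(above) if above else k_max
    d_minus = abs(trigger - ladder[k_minus])
    d_plus = abs(trigger - ladder[k_plus])
    k_c = k_minus if d_minus <= d_plus + TIE_TOL else k_plus
    return OptimalKResult(
        gamma=gamma, trigger=trigger, ladder=ladder,
        k_minus=k_minus, k_plus=k_plus, k_c=k_c,
    )
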