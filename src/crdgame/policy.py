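"""Optimal allocation of the incentive budget between reward and punishment.

Because the defector-advantage ``f_D - f_C`` is linear in the reward weight
``w``, the budget split minimizing it at each population state ``k`` is
bang-bang: all reward or all punishment, decided by the sign of a single
hypergeometric sum (the per-unit advantage of rewarding over sanctioning).
That sum decreases in ``k`` and has one root, so the optimal state-dependent
policy is a *switch*: pure reward while cooperators are scarce, pure
punishment once their fraction ``k/Z`` exceeds the switching point ``s*``.

``s*`` depends only on the population and group sizes and on the efficiency
ratio ``a/b`` — not on the threshold ``M``, the risk ``r``, the cost ``c``
or the budget ``delta``, none of which enter the sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .game import GameParams, IncentivePolicy

__all__ = [
    "SwitchingPolicy",
    "switching_objective",
    "optimal_switching_point",
    "optimal_w_per_state",
]

# tolerance for the runtime monotonicity check on the objective
_MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class SwitchingPolicy:
    """Reward-then-punish policy switching at the cooperator fraction ``s``.

    States with ``k/Z <= s`` receive pure reward (w = 1); strictly above
    the switching point the whole budget goes to punishment (w = 0).  With
    ``s = 0`` the policy is pure punishment everywhere, with ``s = 1`` pure
    reward everywhere.
    """

    s: float
    Z: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"switching fraction s must lie in [0, 1], got {self.s}")
        if self.Z <= 0:
            raise ValueError(f"population size Z must be positive, got {self.Z}")

    @property
    def k_switch(self) -> int:
        """Smallest state at which punishment applies (may exceed Z)."""
        return math.floor(self.s * self.Z) + 1

    def w(self, k: int) -> float:
        return 1.0 if k < self.k_switch else 0.0

    def incentive_policy(
        self, delta: float, a: float = 1.0, b: float = 1.0
    ) -> IncentivePolicy:
        """Package the switching rule as an :class:`IncentivePolicy`."""
        return IncentivePolicy(delta=delta, a=a, b=b, weight_rule=self.w)


def switching_objective(k: int, params: GameParams, a: float, b: float) -> float:
    """Per-unit-budget advantage of rewarding over sanctioning at state ``k``.

    The hypergeometric expectation, over a focal cooperator's co-players,
    of ``a/(j+1) - (b/(N-j)) * (k/(k-j)) * ((Z-k-N+1+j)/(Z-k))``.  Positive
    means spending the budget on rewards reduces the defector advantage
    more than sanctions would; negative means the reverse.  Defined for
    interior states ``1 <= k <= Z-1`` where both strategies are present.
    """
    Z, N = params.Z, params.N
    if not 1 <= k <= Z - 1:
        raise ValueError(f"switching objective requires 1 <= k <= Z-1, got k={k}")
    if a < 0 or b < 0:
        raise ValueError("efficiencies a, b must be >= 0")
    j = np.arange(N)
    weights = hypergeom.pmf(j, Z - 1, k - 1, N - 1)
    term = np.zeros(N)
    support = weights > 0
    js = j[support]
    # on the support j <= k-1 and N-1-j <= Z-k, so k-j >= 1 and the last
    # factor is non-negative; no division by zero can occur
    term[support] = a / (js + 1) - (b / (N - js)) * (k / (k - js)) * (
        (Z - k - N + 1 + js) / (Z - k)
    )
    return float(weights @ term)


def _objective_profile(params: GameParams, a: float, b: float) -> np.ndarray:
    """Objective over k = 1..Z-1, with the single-root claim checked.

    The objective is homogeneous of degree 1 in (a, b), so the pair is
    normalized by its maximum first: the root location — all that matters
    here — is exactly invariant under joint rescaling, including in
    floating point.
    """
    scale = max(a, b)
    a, b = a / scale, b / scale
    vals = np.array(
        [switching_objective(k, params, a, b) for k in range(1, params.Z)]
    )
    if np.any(np.diff(vals) > _MONOTONE_TOL):
        raise RuntimeError(
            "switching objective is not decreasing in k for these parameters; "
            "the single-root assumption does not hold"
        )
    return vals


def optimal_switching_point(params: GameParams, a: float, b: float) -> float:
    """Optimal switching fraction ``s*`` for efficiencies ``a`` (reward) and
    ``b`` (punishment).

    ``s*`` is the largest cooperator fraction still rewarded: the objective
    is evaluated at every interior state and ``s* = k/Z`` for the last
    state with a non-negative value (ties broken toward reward).  Returns
    1.0 if the objective never turns negative (always reward, e.g. b = 0)
    and 0.0 if it is negative already at k = 1 (always punish, e.g. a = 0).
    """
    if a < 0 or b < 0:
        raise ValueError("efficiencies a, b must be >= 0")
    if a == 0 and b == 0:
        raise ValueError("a and b cannot both be zero (objective identically zero)")
    vals = _objective_profile(params, a, b)
    nonneg = np.flatnonzero(vals >= 0)
    if nonneg.size == 0:
        return 0.0
    k_last = int(nonneg[-1]) + 1  # vals[i] corresponds to state k = i + 1
    if k_last == params.Z - 1:
        return 1.0
    return k_last / params.Z


def optimal_w_per_state(k: int, params: GameParams, a: float, b: float) -> float:
    """Advantage-minimizing reward weight at state ``k``: 1.0 or 0.0.

    The objective is linear in ``w``, so the optimum sits at a boundary;
    a weight of 1 is kept when the objective is exactly zero.
    """
    return 1.0 if switching_objective(k, params, a, b) >= 0 else 0.0
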