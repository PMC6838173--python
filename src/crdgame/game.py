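"""Single-round payoffs of the N-player collective-risk dilemma.

A group of ``N`` players succeeds if at least ``M`` of them cooperate, each
cooperator paying a fraction ``c`` of the endowment ``B``.  A group that
misses the threshold loses the remaining endowment with probability ``r``
(the *risk*).  An institution may additionally spend a fixed per-group
budget ``N*delta`` on rewarding cooperators (a fraction ``w`` of it) and
sanctioning defectors (the remaining ``1 - w``), with efficiencies ``a``
and ``b`` respectively.  The budget is divided among the individuals
actually present: each of the ``j`` cooperators in a group receives
``a*w*N*delta / j`` and each of the ``N - j`` defectors loses
``b*(1-w)*N*delta / (N - j)``.  No cap is applied when a share becomes
large because few recipients are present — that blow-up is a deliberate
feature of the incentive scheme, responsible for the emergence of a
near-full-cooperation equilibrium under strong sanctioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "GameParams",
    "IncentivePolicy",
    "heaviside",
    "payoff_defector_base",
    "payoff_cooperator_base",
    "payoff_defector_incentivized",
    "payoff_cooperator_incentivized",
]


@dataclass(frozen=True)
class GameParams:
    """Structural constants of the collective-risk dilemma.

    Parameters
    ----------
    Z : int
        Population size.
    N : int
        Group size (groups are sampled from the population without
        replacement).
    M : int
        Success threshold: minimum number of cooperators a group needs.
    B : float
        Initial endowment per player (payoff units).
    c : float
        Cost of cooperation, as a fraction of the endowment (``0 <= c <= 1``).
    r : float
        Risk: probability that a group below the threshold loses the
        remaining endowment (``0 <= r <= 1``).
    """

    Z: int
    N: int
    M: int
    B: float = 1.0
    c: float = 0.1
    r: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.N <= self.Z):
            raise ValueError(f"require 0 < N <= Z, got N={self.N}, Z={self.Z}")
        if not (0 < self.M <= self.N):
            raise ValueError(f"require 0 < M <= N, got M={self.M}, N={self.N}")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError(f"cost fraction c must lie in [0, 1], got {self.c}")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError(f"risk r must lie in [0, 1], got {self.r}")
        if not self.B > 0:
            raise ValueError(f"endowment B must be positive, got {self.B}")


WeightRule = Union[float, Callable[[int], float]]


@dataclass(frozen=True)
class IncentivePolicy:
    """Institutional incentive scheme: budget, efficiencies and weight rule.

    Parameters
    ----------
    delta : float
        Per-capita incentive budget (payoff units); the total group budget
        is ``N * delta``.
    a, b : float
        Efficiency of reward and punishment (payoff gained/lost per unit
        of budget spent).
    weight_rule : float or callable
        Fraction ``w`` of the budget spent on rewards.  Either a constant
        in ``[0, 1]`` or a map from the population state ``k`` (number of
        cooperators in the whole population) to ``w``.  The weight is a
        population-level decision: groups do not observe their own
        composition to set it.
    """

    delta: float = 0.0
    a: float = 1.0
    b: float = 1.0
    weight_rule: WeightRule = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"budget delta must be >= 0, got {self.delta}")
        if self.a < 0 or self.b < 0:
            raise ValueError("efficiencies a, b must be >= 0")
        if isinstance(self.weight_rule, (int, float)) and not (
            0.0 <= float(self.weight_rule) <= 1.0
        ):
            raise ValueError(f"constant weight must lie in [0, 1], got {self.weight_rule}")

    def w(self, k: int) -> float:
        """Reward fraction applied when the population holds ``k`` cooperators."""
        if callable(self.weight_rule):
            w = float(self.weight_rule(k))
        else:
            w = float(self.weight_rule)
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"weight rule returned w={w} outside [0, 1] at k={k}")
        return w

    # -- common schemes ---------------------------------------------------
    @classmethod
    def none(cls) -> "IncentivePolicy":
        """No incentives (zero budget)."""
        return cls(delta=0.0)

    @classmethod
    def pure_reward(cls, delta: float, a: float = 1.0, b: float = 1.0) -> "IncentivePolicy":
        """Whole budget spent on rewarding cooperators (w = 1)."""
        return cls(delta=delta, a=a, b=b, weight_rule=1.0)

    @classmethod
    def pure_punishment(cls, delta: float, a: float = 1.0, b: float = 1.0) -> "IncentivePolicy":
        """Whole budget spent on sanctioning defectors (w = 0)."""
        return cls(delta=delta, a=a, b=b, weight_rule=0.0)


def heaviside(x: float) -> int:
    """Step function with the right-continuous convention: 1 iff ``x >= 0``.

    The threshold being exactly met counts as collective success.
    """
    if not np.isfinite(x):
        raise ValueError(f"heaviside requires a finite argument, got {x}")
    return 1 if x >= 0 else 0


def _check_j(j: int, lo: int, hi: int, who: str) -> None:
    if not lo <= j <= hi:
        raise ValueError(f"{who}: cooperator count j={j} outside [{lo}, {hi}]")


def payoff_defector_base(j: int, params: GameParams) -> float:
    """Payoff of a defector in a group with ``j`` cooperators, no incentives.

    The defector keeps the full endowment ``B`` if the group reaches the
    threshold, and its expected value ``B*(1 - r)`` otherwise.
    """
    _check_j(j, 0, params.N, "payoff_defector_base")
    th = heaviside(j - params.M)
    return params.B * (th + (1.0 - params.r) * (1 - th))


def payoff_cooperator_base(j: int, params: GameParams) -> float:
    """Payoff of a cooperator in a group with ``j`` cooperators, no incentives.

    Equal to the defector's payoff minus the contribution ``c*B``.  Requires
    ``j >= 1``: the focal cooperator is part of the count.
    """
    _check_j(j, 1, params.N, "payoff_cooperator_base")
    return payoff_defector_base(j, params) - params.c * params.B


def payoff_defector_incentivized(
    j: int, params: GameParams, policy: IncentivePolicy, w: float
) -> float:
    """Defector payoff including the per-defector share of the sanction budget.

    Each of the ``N - j`` defectors loses ``b*(1-w)*N*delta / (N - j)``.
    Requires ``j <= N - 1`` (at least one defector present).
    """
    _check_j(j, 0, params.N - 1, "payoff_defector_incentivized")
    base = payoff_defector_base(j, params)
    if policy.delta == 0.0:
        return base
    return base - policy.b * (1.0 - w) * params.N * policy.delta / (params.N - j)


def payoff_cooperator_incentivized(
    j: int, params: GameParams, policy: IncentivePolicy, w: float
) -> float:
    """Cooperator payoff including the per-cooperator share of the reward budget.

    Each of the ``j`` cooperators receives ``a*w*N*delta / j``.  Requires
    ``j >= 1`` (at least one cooperator present).
    """
    _check_j(j, 1, params.N, "payoff_cooperator_incentivized")
    base = payoff_cooperator_base(j, params)
    if policy.delta == 0.0:
        return base
    return base + policy.a * w * params.N * policy.delta / j
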