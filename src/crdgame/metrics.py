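"""Group success and average group achievement.

``group_success_prob(k)`` is the probability that a group of ``N`` drawn
without replacement from the whole population (``k`` cooperators among
``Z``) contains at least ``M`` cooperators — a census quantity, so no focal
individual is excluded.  Weighting it by the stationary distribution gives
the average group achievement ``eta_G``, the headline cooperation metric.

Success here means *reaching the threshold*.  Groups below the threshold
that happen to escape the risk are not counted as successes by default;
the ``count_risk_survival`` flag switches to the alternative reading
``a_G + (1 - a_G) * (1 - r)`` in which sub-threshold groups survive with
probability ``1 - r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .game import GameParams
from .evolution import DynamicsParams, stationary_distribution
from .game import IncentivePolicy

__all__ = [
    "AchievementResult",
    "group_success_prob",
    "group_success_profile",
    "group_achievement",
    "average_group_achievement",
]


def group_success_prob(
    k: int, params: GameParams, count_risk_survival: bool = False
) -> float:
    """Probability that a randomly formed group reaches the threshold.

    ``sum_{j=M..N} C(k,j) C(Z-k,N-j) / C(Z,N)`` — the hypergeometric upper
    tail at ``M``.
    """
    if not 0 <= k <= params.Z:
        raise ValueError(f"state k={k} outside [0, {params.Z}]")
    p = float(hypergeom.sf(params.M - 1, params.Z, k, params.N))
    if count_risk_survival:
        p = p + (1.0 - p) * (1.0 - params.r)
    return p


def group_success_profile(
    params: GameParams, count_risk_survival: bool = False
) -> np.ndarray:
    """Vector of ``group_success_prob`` over all states k = 0..Z."""
    kk = np.arange(params.Z + 1)
    a_G = hypergeom.sf(params.M - 1, params.Z, kk, params.N)
    if count_risk_survival:
        a_G = a_G + (1.0 - a_G) * (1.0 - params.r)
    return np.asarray(a_G, dtype=float)


def group_achievement(p_bar: np.ndarray, a_G: np.ndarray) -> float:
    """Stationary-weighted mean success probability, ``eta_G = sum p_k a_G(k)``."""
    p_bar = np.asarray(p_bar, dtype=float)
    a_G = np.asarray(a_G, dtype=float)
    if p_bar.shape != a_G.shape:
        raise ValueError(
            f"length mismatch: p_bar has {p_bar.shape}, a_G has {a_G.shape}"
        )
    return float(p_bar @ a_G)


@dataclass(frozen=True)
class AchievementResult:
    """Per-state success probabilities and their stationary average."""

    a_G: np.ndarray
    eta_G: float


def average_group_achievement(
    params: GameParams,
    policy: IncentivePolicy,
    dyn: DynamicsParams,
    count_risk_survival: bool = False,
) -> AchievementResult:
    """Full pipeline: stationary distribution, success profile, and eta_G."""
    p_bar = stationary_distribution(params, policy, dyn)
    a_G = group_success_profile(params, count_risk_survival=count_risk_survival)
    return AchievementResult(a_G=a_G, eta_G=group_achievement(p_bar, a_G))
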