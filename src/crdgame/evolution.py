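"""Finite-population social-learning dynamics of the collective-risk dilemma.

The population of ``Z`` individuals holds ``k`` cooperators; its state
evolves by a birth-death Markov chain.  Fitness is the expected single-round
payoff over the hypergeometric distribution of group compositions (groups
of ``N`` sampled without replacement).  Strategy revision follows the
pairwise-comparison (Fermi) rule with selection intensity ``beta``,
perturbed by a strategy-exploration rate ``mu`` that keeps the chain
ergodic.  From the per-state transition probabilities this module derives
the gradient of selection, its interior sign changes (the finite-population
analogues of fixed points) and the stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import hypergeom

from .game import (
    GameParams,
    IncentivePolicy,
    payoff_cooperator_incentivized,
    payoff_defector_incentivized,
)

__all__ = [
    "DynamicsParams",
    "ChainProfile",
    "Equilibrium",
    "group_composition_prob",
    "fitness",
    "imitation_prob",
    "transition_probs",
    "gradient",
    "stationary_distribution",
    "find_equilibria",
    "chain_profile",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Selection intensity ``beta`` (inverse payoff units) and exploration
    rate ``mu`` (per-revision probability of adopting a random strategy)."""

    beta: float = 5.0
    mu: float = 0.01

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"selection intensity beta must be >= 0, got {self.beta}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"exploration rate mu must lie in [0, 1], got {self.mu}")


def group_composition_prob(
    j: int, k: int, focal: Literal["C", "D"], params: GameParams
) -> float:
    """Probability that a focal individual's ``N - 1`` co-players contain
    exactly ``j`` cooperators.

    Co-players are drawn without replacement from the other ``Z - 1``
    individuals, of whom ``k - 1`` (focal cooperator) or ``k`` (focal
    defector) cooperate.  Out-of-range compositions have probability 0.
    """
    Z, N = params.Z, params.N
    if not 0 <= j <= N - 1:
        raise ValueError(f"co-player cooperator count j={j} outside [0, {N - 1}]")
    if not 0 <= k <= Z:
        raise ValueError(f"state k={k} outside [0, {Z}]")
    if focal == "C":
        if k < 1:
            raise ValueError("focal cooperator requires k >= 1")
        avail = k - 1
    elif focal == "D":
        if k > Z - 1:
            raise ValueError("focal defector requires k <= Z - 1")
        avail = k
    else:
        raise ValueError(f"focal must be 'C' or 'D', got {focal!r}")
    return float(hypergeom.pmf(j, Z - 1, avail, N - 1))


def _payoff_vectors(
    k: int, params: GameParams, policy: IncentivePolicy
) -> tuple[np.ndarray, np.ndarray]:
    """Per-composition payoffs Pi_C(j+1), Pi_D(j) for j = 0..N-1 at state k."""
    w = policy.w(k)
    N = params.N
    pi_C = np.array(
        [payoff_cooperator_incentivized(j + 1, params, policy, w) for j in range(N)]
    )
    pi_D = np.array(
        [payoff_defector_incentivized(j, params, policy, w) for j in range(N)]
    )
    return pi_C, pi_D


def fitness(
    k: int, params: GameParams, policy: IncentivePolicy, which: Literal["C", "D"]
) -> float:
    """Expected single-round payoff of a cooperator or defector at state ``k``.

    The expectation runs over the hypergeometric distribution of the focal
    individual's co-players; the focal cooperator's group holds ``j + 1``
    cooperators in total, the focal defector's ``j``.  Evaluating the
    fitness of an absent strategy (``C`` at k=0, ``D`` at k=Z) is an error.
    """
    Z, N = params.Z, params.N
    if not 0 <= k <= Z:
        raise ValueError(f"state k={k} outside [0, {Z}]")
    if which == "C" and k < 1:
        raise ValueError("fitness of a cooperator undefined at k=0")
    if which == "D" and k > Z - 1:
        raise ValueError("fitness of a defector undefined at k=Z")

    j = np.arange(N)
    pi_C, pi_D = _payoff_vectors(k, params, policy)
    if which == "C":
        weights = hypergeom.pmf(j, Z - 1, k - 1, N - 1)
        return float(weights @ pi_C)
    weights = hypergeom.pmf(j, Z - 1, k, N - 1)
    return float(weights @ pi_D)


def imitation_prob(f_role_model: float, f_focal: float, dyn: DynamicsParams) -> float:
    """Fermi probability that the focal adopts the role model's strategy.

    ``[1 + exp(-beta * (f_role_model - f_focal))]^-1``; saturates smoothly
    to 0/1 for large ``|beta * df|`` instead of overflowing.
    """
    return float(expit(dyn.beta * (f_role_model - f_focal)))


def transition_probs(
    k: int,
    params: GameParams,
    policy: IncentivePolicy,
    dyn: DynamicsParams,
    with_mutation: bool = False,
) -> tuple[float, float]:
    """Probabilities ``(T_plus, T_minus)`` of gaining / losing one cooperator.

    Without mutation: ``T±(k) = (k/Z)((Z-k)/Z) * Fermi(±beta*(f_C - f_D))``,
    where the demographic prefactor short-circuits to 0 at the monomorphic
    states so fitnesses of absent strategies are never evaluated.  With
    mutation the exploration-mixed probabilities
    ``T_mu± = (1-mu) T± + mu * (opposite fraction)`` are returned.
    """
    Z = params.Z
    if not 0 <= k <= Z:
        raise ValueError(f"state k={k} outside [0, {Z}]")
    if k == 0 or k == Z:
        t_plus, t_minus = 0.0, 0.0
    else:
        df = fitness(k, params, policy, "C") - fitness(k, params, policy, "D")
        pref = (k / Z) * ((Z - k) / Z)
        t_plus = pref * float(expit(dyn.beta * df))
        t_minus = pref * float(expit(-dyn.beta * df))
    if not with_mutation:
        return t_plus, t_minus
    mu = dyn.mu
    return (
        (1.0 - mu) * t_plus + mu * (Z - k) / Z,
        (1.0 - mu) * t_minus + mu * k / Z,
    )


def _fitness_profiles(
    params: GameParams, policy: IncentivePolicy
) -> tuple[np.ndarray, np.ndarray]:
    """f_C, f_D over k = 0..Z; NaN where the strategy is absent."""
    Z = params.Z
    f_C = np.full(Z + 1, np.nan)
    f_D = np.full(Z + 1, np.nan)
    for k in range(1, Z + 1):
        f_C[k] = fitness(k, params, policy, "C")
    for k in range(0, Z):
        f_D[k] = fitness(k, params, policy, "D")
    return f_C, f_D


def _transition_profiles(
    params: GameParams, policy: IncentivePolicy, dyn: DynamicsParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Z = params.Z
    f_C, f_D = _fitness_profiles(params, policy)
    kk = np.arange(Z + 1)
    pref = (kk / Z) * ((Z - kk) / Z)
    df = np.zeros(Z + 1)
    df[1:Z] = f_C[1:Z] - f_D[1:Z]
    t_plus = pref * expit(dyn.beta * df)
    t_minus = pref * expit(-dyn.beta * df)
    t_plus[[0, Z]] = 0.0
    t_minus[[0, Z]] = 0.0
    t_mu_plus = (1.0 - dyn.mu) * t_plus + dyn.mu * (Z - kk) / Z
    t_mu_minus = (1.0 - dyn.mu) * t_minus + dyn.mu * kk / Z
    return f_C, f_D, t_plus, t_minus, t_mu_plus, t_mu_minus


def gradient(
    params: GameParams,
    policy: IncentivePolicy,
    dyn: DynamicsParams,
    with_mutation: bool = False,
) -> np.ndarray:
    """Gradient of selection ``G(k) = T+(k) - T-(k)`` over k = 0..Z.

    Positive values mean cooperators are more likely to increase.  By
    default the mutation-free probabilities are used (the gradient is
    defined from the selection process alone); set ``with_mutation`` to
    include the exploration terms.
    """
    _, _, t_plus, t_minus, t_mu_plus, t_mu_minus = _transition_profiles(
        params, policy, dyn
    )
    if with_mutation:
        return t_mu_plus - t_mu_minus
    return t_plus - t_minus


def stationary_distribution(
    params: GameParams, policy: IncentivePolicy, dyn: DynamicsParams
) -> np.ndarray:
    """Stationary distribution of the exploration-augmented birth-death chain.

    Uses the closed-form product formula for reversible birth-death chains,
    ``p_k ∝ prod_{i=1..k} T_mu+(i-1) / T_mu-(i)``, accumulated in log space
    for robustness at strong selection, then normalized.  Requires
    ``mu > 0``: without exploration the chain has absorbing monomorphic
    states and no unique stationary law.
    """
    if dyn.mu <= 0.0:
        raise ValueError(
            "stationary distribution requires mu > 0 (the mutation-free chain "
            "is absorbing)"
        )
    *_, t_mu_plus, t_mu_minus = _transition_profiles(params, policy, dyn)
    # T_mu+ > 0 for k < Z and T_mu- > 0 for k > 0 whenever mu > 0
    log_ratio = np.log(t_mu_plus[:-1]) - np.log(t_mu_minus[1:])
    log_p = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


@dataclass(frozen=True)
class Equilibrium:
    """An interior sign change of the gradient between states ``k`` and ``k+1``.

    ``stable`` marks a +→− change (coexistence attractor); unstable, a −→+
    change (coordination barrier).
    """

    k_lower: int
    k_upper: int
    stable: bool

    @property
    def kind(self) -> str:
        return "coexistence" if self.stable else "coordination"

    @property
    def location(self) -> float:
        """Midpoint of the bracketing pair, as a fraction of Z-free states."""
        return 0.5 * (self.k_lower + self.k_upper)


def find_equilibria(G: Sequence[float]) -> list[Equilibrium]:
    """Locate the finite-population analogues of fixed points.

    Scans the interior states for adjacent pairs with strictly opposite
    gradient signs: +→− is a stable (coexistence) equilibrium, −→+ an
    unstable (coordination) one.
    """
    G = np.asarray(G, dtype=float)
    out: list[Equilibrium] = []
    for k in range(1, len(G) - 2):
        if G[k] > 0 and G[k + 1] < 0:
            out.append(Equilibrium(k, k + 1, stable=True))
        elif G[k] < 0 and G[k + 1] > 0:
            out.append(Equilibrium(k, k + 1, stable=False))
    return out


@dataclass(frozen=True)
class ChainProfile:
    """Per-state summary of the evolutionary Markov chain over k = 0..Z."""

    params: GameParams
    policy: IncentivePolicy
    dyn: DynamicsParams
    f_C: np.ndarray
    f_D: np.ndarray
    T_plus: np.ndarray
    T_minus: np.ndarray
    T_mu_plus: np.ndarray
    T_mu_minus: np.ndarray
    G: np.ndarray
    p_bar: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return np.arange(self.params.Z + 1)

    def equilibria(self) -> list[Equilibrium]:
        return find_equilibria(self.G)

    def to_frame(self) -> pd.DataFrame:
        Z = self.params.Z
        return pd.DataFrame(
            {
                "k": self.k,
                "k_over_Z": self.k / Z,
                "f_C": self.f_C,
                "f_D": self.f_D,
                "T_plus": self.T_plus,
                "T_minus": self.T_minus,
                "T_mu_plus": self.T_mu_plus,
                "T_mu_minus": self.T_mu_minus,
                "G": self.G,
                "p_bar": self.p_bar,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def chain_profile(
    params: GameParams, policy: IncentivePolicy, dyn: DynamicsParams
) -> ChainProfile:
    """Assemble fitnesses, transitions, gradient and stationary law per state."""
    f_C, f_D, t_plus, t_minus, t_mu_plus, t_mu_minus = _transition_profiles(
        params, policy, dyn
    )
    p_bar = stationary_distribution(params, policy, dyn)
    return ChainProfile(
        params=params,
        policy=policy,
        dyn=dyn,
        f_C=f_C,
        f_D=f_D,
        T_plus=t_plus,
        T_minus=t_minus,
        T_mu_plus=t_mu_plus,
        T_mu_minus=t_mu_minus,
        G=t_plus - t_minus,
        p_bar=p_bar,
    )
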