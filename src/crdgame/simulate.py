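"""Agent-based Monte Carlo simulation of the social-learning process.

Independent stochastic realization of the imitation dynamics whose
per-state rates the analytic birth-death chain encodes.  Each elementary
event picks one focal individual at random; with probability ``mu`` the
focal explores (adopts the other strategy), otherwise a role model is
drawn uniformly from the population (imitating oneself changes nothing)
and its strategy adopted with the Fermi probability.  The event-level
probabilities of gaining or losing one cooperator then coincide exactly
with the exploration-mixed transition probabilities of the analytic chain,
so long-run occupancies and one-step frequencies provide an end-to-end
check of the closed-form machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .evolution import DynamicsParams, _fitness_profiles
from .game import GameParams, IncentivePolicy

__all__ = [
    "TrajectorySample",
    "simulate",
    "empirical_distribution",
    "onestep_frequencies",
]

_BLOCK = 1 << 16  # events per pre-drawn block of uniforms


@dataclass(frozen=True)
class TrajectorySample:
    """A recorded trajectory of population states (cooperator counts)."""

    seed: int
    steps: int
    burn_in: int
    Z: int
    states: np.ndarray  # k after each elementary event, length `steps`

    def __post_init__(self) -> None:
        if self.states.size and (
            self.states.min() < 0 or self.states.max() > self.Z
        ):
            raise ValueError("recorded states outside [0, Z]")

    @property
    def kept(self) -> np.ndarray:
        """States after discarding the burn-in prefix."""
        return self.states[self.burn_in :]


def simulate(
    params: GameParams,
    policy: IncentivePolicy,
    dyn: DynamicsParams,
    steps: int,
    seed: int,
    burn_in: int = 0,
    k0: int | None = None,
) -> TrajectorySample:
    """Run ``steps`` elementary imitation/exploration events.

    Parameters
    ----------
    steps, burn_in : int
        Number of events to simulate and the prefix to discard in
        summaries (``steps > burn_in >= 0``).
    seed : int
        Seed for the ``numpy.random.default_rng`` generator; identical
        seeds and parameters reproduce identical trajectories.
    k0 : int, optional
        Initial cooperator count; defaults to ``Z // 2``.
    """
    Z = params.Z
    if not steps > burn_in >= 0:
        raise ValueError(f"require steps > burn_in >= 0, got {steps}, {burn_in}")
    k = Z // 2 if k0 is None else int(k0)
    if not 0 <= k <= Z:
        raise ValueError(f"initial state k0={k} outside [0, {Z}]")

    f_C, f_D = _fitness_profiles(params, policy)
    # Fermi acceptance probabilities per interior state (NaN-safe: the
    # boundary entries are never indexed because focal and model strategies
    # cannot differ there)
    df = np.zeros(Z + 1)
    df[1:Z] = f_C[1:Z] - f_D[1:Z]
    p_adopt_C = expit(dyn.beta * df)  # D focal imitating a C model
    p_adopt_D = expit(-dyn.beta * df)  # C focal imitating a D model

    rng = np.random.default_rng(seed)
    states = np.empty(steps, dtype=np.int32)
    mu = dyn.mu
    pos = 0
    while pos < steps:
        n = min(_BLOCK, steps - pos)
        u = rng.random((n, 4))
        for i in range(n):
            focal_is_C = u[i, 0] * Z < k
            if u[i, 1] < mu:
                # exploration: switch to the other strategy
                k += -1 if focal_is_C else 1
            else:
                model_is_C = u[i, 2] * Z < k
                if focal_is_C and not model_is_C:
                    if u[i, 3] < p_adopt_D[k]:
                        k -= 1
                elif model_is_C and not focal_is_C:
                    if u[i, 3] < p_adopt_C[k]:
                        k += 1
            states[pos + i] = k
        pos += n

    return TrajectorySample(seed=seed, steps=steps, burn_in=burn_in, Z=Z, states=states)


def empirical_distribution(sample: TrajectorySample, Z: int | None = None) -> np.ndarray:
    """Normalized occupancy histogram of the post-burn-in states over 0..Z."""
    Z = sample.Z if Z is None else Z
    kept = sample.kept
    if kept.size == 0:
        raise ValueError("no states remain after burn-in")
    counts = np.bincount(kept, minlength=Z + 1).astype(float)
    return counts / counts.sum()


def onestep_frequencies(
    sample: TrajectorySample,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state counts of (up-moves, down-moves, visits) along the trajectory.

    Transitions are attributed to the state they depart from; the burn-in
    prefix is excluded.  Dividing the move counts by the visit counts gives
    empirical estimates of the chain's per-event transition probabilities.
    """
    kept = sample.kept
    if kept.size < 2:
        raise ValueError("need at least two post-burn-in states")
    frm, to = kept[:-1], kept[1:]
    Z = sample.Z
    visits = np.bincount(frm, minlength=Z + 1).astype(float)
    ups = np.bincount(frm[to == frm + 1], minlength=Z + 1).astype(float)
    downs = np.bincount(frm[to == frm - 1], minlength=Z + 1).astype(float)
    return ups, downs, visits
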