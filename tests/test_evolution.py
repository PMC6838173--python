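"""Fitness, transitions, gradient and stationary distribution of the chain."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from crdgame import (
    DynamicsParams,
    GameParams,
    IncentivePolicy,
    chain_profile,
    find_equilibria,
    fitness,
    gradient,
    group_composition_prob,
    imitation_prob,
    stationary_distribution,
    transition_probs,
)
from crdgame.game import (
    payoff_cooperator_incentivized,
    payoff_defector_incentivized,
)


# ---------------------------------------------------------------- oracles
def fitness_by_enumeration(k, params, policy, which):
    """Average payoff over every possible co-player subset, exhaustively.

    The other Z-1 individuals are laid out explicitly and all
    C(Z-1, N-1) co-player combinations enumerated with equal weight.
    """
    Z, N = params.Z, params.N
    w = policy.w(k)
    others_c = k - 1 if which == "C" else k
    others = [1] * others_c + [0] * (Z - 1 - others_c)
    total, count = 0.0, 0
    for combo in itertools.combinations(range(Z - 1), N - 1):
        j = sum(others[i] for i in combo)
        if which == "C":
            total += payoff_cooperator_incentivized(j + 1, params, policy, w)
        else:
            total += payoff_defector_incentivized(j, params, policy, w)
        count += 1
    return total / count


def stationary_by_eigenvector(params, policy, dyn):
    """Leading left-eigenvector of the full tridiagonal transition matrix."""
    Z = params.Z
    tp = np.empty(Z + 1)
    tm = np.empty(Z + 1)
    for k in range(Z + 1):
        tp[k], tm[k] = transition_probs(k, params, policy, dyn, with_mutation=True)
    P = np.diag(1.0 - tp - tm)
    P += np.diag(tp[:-1], 1) + np.diag(tm[1:], -1)
    vals, vecs = np.linalg.eig(P.T)
    lead = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, lead])
    v = np.abs(v)
    return v / v.sum()


# ------------------------------------------------- group composition prob
def test_composition_prob_normalizes():
    params = GameParams(Z=12, N=5, M=2)
    for k, focal in [(0, "D"), (3, "C"), (7, "D"), (12, "C")]:
        total = sum(
            group_composition_prob(j, k, focal, params) for j in range(params.N)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def test_composition_prob_point_mass_without_cooperators():
    params = GameParams(Z=12, N=5, M=2)
    assert group_composition_prob(0, 0, "D", params) == pytest.approx(1.0)
    for j in range(1, params.N):
        assert group_composition_prob(j, 0, "D", params) == 0.0


def test_composition_prob_matches_enumeration():
    """Z=6, N=3, k=3, focal C: P(one C co-player) = C(2,1)C(3,1)/C(5,2)."""
    params = GameParams(Z=6, N=3, M=1)
    assert group_composition_prob(1, 3, "C", params) == pytest.approx(6 / 10)


def test_composition_prob_preconditions():
    params = GameParams(Z=6, N=3, M=1)
    with pytest.raises(ValueError):
        group_composition_prob(0, 0, "C", params)
    with pytest.raises(ValueError):
        group_composition_prob(0, 6, "D", params)
    with pytest.raises(ValueError):
        group_composition_prob(3, 3, "C", params)  # j > N-1


# ---------------------------------------------------------------- fitness
def test_fitness_difference_without_risk_is_cost():
    params = GameParams(Z=30, N=6, M=3, B=1.0, c=0.1, r=0.0)
    policy = IncentivePolicy.none()
    for k in (1, 10, 29):
        df = fitness(k, params, policy, "D") - fitness(k, params, policy, "C")
        assert df == pytest.approx(params.c * params.B, abs=1e-12)


def test_lone_cooperator_never_reaches_threshold():
    params = GameParams(Z=50, N=10, M=5, B=1.0, c=0.1, r=0.5)
    assert fitness(1, params, IncentivePolicy.none(), "C") == pytest.approx(0.4)


@pytest.mark.parametrize("delta,w", [(0.0, 1.0), (0.05, 1.0), (0.05, 0.0), (0.03, 0.6)])
def test_fitness_matches_exhaustive_enumeration(delta, w):
    params = GameParams(Z=8, N=4, M=2, B=1.0, c=0.2, r=0.7)
    policy = IncentivePolicy(delta=delta, a=1.3, b=0.8, weight_rule=w)
    for k in range(1, params.Z):
        for which in ("C", "D"):
            assert fitness(k, params, policy, which) == pytest.approx(
                fitness_by_enumeration(k, params, policy, which), abs=1e-12
            )


def test_fitness_of_absent_strategy_is_error():
    params = GameParams(Z=10, N=4, M=2)
    with pytest.raises(ValueError):
        fitness(0, params, IncentivePolicy.none(), "C")
    with pytest.raises(ValueError):
        fitness(10, params, IncentivePolicy.none(), "D")


def test_budget_monotonicity_of_fitness():
    """More reward budget never hurts cooperators; more sanction budget
    never helps defectors."""
    params = GameParams(Z=20, N=8, M=4)
    deltas = [0.0, 0.01, 0.05, 0.2]
    for k in range(1, params.Z):
        f_C = [
            fitness(k, params, IncentivePolicy.pure_reward(d), "C") for d in deltas
        ]
        f_D = [
            fitness(k, params, IncentivePolicy.pure_punishment(d), "D") for d in deltas
        ]
        assert np.all(np.diff(f_C) >= -1e-15)
        assert np.all(np.diff(f_D) <= 1e-15)


# ----------------------------------------------------- imitation and T±
def test_imitation_prob_limits():
    assert imitation_prob(1.0, 1.0, DynamicsParams(beta=5)) == pytest.approx(0.5)
    assert imitation_prob(2.0, -1.0, DynamicsParams(beta=0)) == pytest.approx(0.5)
    assert imitation_prob(1.0, 0.0, DynamicsParams(beta=1e6)) == pytest.approx(1.0)
    assert imitation_prob(0.0, 1.0, DynamicsParams(beta=1e6)) == pytest.approx(0.0)
    # no overflow at extreme fitness gaps
    assert imitation_prob(-1e9, 1e9, DynamicsParams(beta=10)) == 0.0


def test_imitation_prob_increasing_in_gap():
    dyn = DynamicsParams(beta=2.0)
    gaps = np.linspace(-3, 3, 13)
    probs = [imitation_prob(g, 0.0, dyn) for g in gaps]
    assert np.all(np.diff(probs) > 0)


def test_transition_probs_boundaries_and_neutral_drift(baseline_params, dyn):
    p = baseline_params
    pol = IncentivePolicy.none()
    assert transition_probs(0, p, pol, dyn) == (0.0, 0.0)
    assert transition_probs(p.Z, p, pol, dyn) == (0.0, 0.0)
    tp, tm = transition_probs(0, p, pol, dyn, with_mutation=True)
    assert tp == pytest.approx(dyn.mu) and tm == 0.0
    tp, tm = transition_probs(p.Z, p, pol, dyn, with_mutation=True)
    assert tp == 0.0 and tm == pytest.approx(dyn.mu)
    # beta = 0: pure drift, T+ = T- = prefactor / 2
    drift = DynamicsParams(beta=0.0, mu=0.01)
    for k in (1, 17, 42):
        tp, tm = transition_probs(k, p, pol, drift)
        pref = (k / p.Z) * ((p.Z - k) / p.Z)
        assert tp == pytest.approx(pref / 2) and tm == pytest.approx(pref / 2)


def test_transition_probs_are_probabilities(baseline_params, dyn):
    p = baseline_params
    pol = IncentivePolicy.pure_punishment(0.02)
    for k in range(p.Z + 1):
        for wm in (False, True):
            tp, tm = transition_probs(k, p, pol, dyn, with_mutation=wm)
            assert 0.0 <= tp <= 1.0 and 0.0 <= tm <= 1.0
            assert tp + tm <= 1.0
        tpm, tmm = transition_probs(k, p, pol, dyn, with_mutation=True)
        if k < p.Z:
            assert tpm > 0
        if k > 0:
            assert tmm > 0


# ---------------------------------------------------------------- gradient
def test_gradient_boundaries_and_defection_dominance(dyn):
    params = GameParams(Z=30, N=6, M=3, r=0.0)
    G = gradient(params, IncentivePolicy.none(), dyn)
    assert G[0] == 0.0 and G[-1] == 0.0
    # without risk, defection dominates: cooperators always decline
    assert np.all(G[1:-1] < 0)


def test_gradient_with_mutation_variant(baseline_params, dyn):
    G = gradient(baseline_params, IncentivePolicy.none(), dyn, with_mutation=True)
    # exploration pushes away from the monomorphic states
    assert G[0] == pytest.approx(dyn.mu)
    assert G[-1] == pytest.approx(-dyn.mu)


def test_find_equilibria_classification():
    assert find_equilibria([0, -1, -2, -1, 0]) == []
    eqs = find_equilibria([0, 1, 1, -1, 0])
    assert len(eqs) == 1 and eqs[0].stable and (eqs[0].k_lower, eqs[0].k_upper) == (2, 3)
    eqs = find_equilibria([0, -1, 1, 2, -1, 0])
    assert [e.stable for e in eqs] == [False, True]
    assert eqs[0].kind == "coordination" and eqs[1].kind == "coexistence"


def test_baseline_has_coordination_then_coexistence(baseline_params, dyn):
    """At the no-incentive baseline the dilemma shows two interior
    equilibria: a coordination barrier followed by a coexistence point."""
    G = gradient(baseline_params, IncentivePolicy.none(), dyn)
    eqs = find_equilibria(G)
    assert len(eqs) == 2
    assert not eqs[0].stable and eqs[1].stable
    assert eqs[0].k_upper <= eqs[1].k_lower


# ---------------------------------------------------- stationary distribution
def test_stationary_requires_exploration(baseline_params):
    with pytest.raises(ValueError):
        stationary_distribution(
            baseline_params, IncentivePolicy.none(), DynamicsParams(beta=5, mu=0.0)
        )


def test_stationary_normalizes(baseline_params, dyn):
    p_bar = stationary_distribution(baseline_params, IncentivePolicy.none(), dyn)
    assert p_bar.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p_bar >= 0)


@pytest.mark.parametrize("delta,w", [(0.0, 1.0), (0.02, 1.0), (0.02, 0.0)])
def test_stationary_matches_eigenvector_oracle(baseline_params, dyn, delta, w):
    pol = IncentivePolicy(delta=delta, weight_rule=w)
    p_prod = stationary_distribution(baseline_params, pol, dyn)
    p_eig = stationary_by_eigenvector(baseline_params, pol, dyn)
    assert np.max(np.abs(p_prod - p_eig)) < 1e-10


def test_detailed_balance(baseline_params, dyn):
    """Birth-death chains are reversible: p_k T+(k) = p_{k+1} T-(k+1)."""
    pol = IncentivePolicy.pure_reward(0.02)
    p_bar = stationary_distribution(baseline_params, pol, dyn)
    for k in range(baseline_params.Z):
        tp, _ = transition_probs(k, baseline_params, pol, dyn, with_mutation=True)
        _, tm = transition_probs(k + 1, baseline_params, pol, dyn, with_mutation=True)
        assert p_bar[k] * tp == pytest.approx(p_bar[k + 1] * tm, abs=1e-12)


def test_full_exploration_is_ehrenfest_urn():
    """At mu = 1 selection is switched off entirely and the chain reduces
    to the Ehrenfest urn, whose stationary law is binomial(Z, 1/2)."""
    params = GameParams(Z=30, N=6, M=3)
    dyn = DynamicsParams(beta=5.0, mu=1.0)
    p_bar = stationary_distribution(params, IncentivePolicy.none(), dyn)
    expected = binom.pmf(np.arange(params.Z + 1), params.Z, 0.5)
    assert np.max(np.abs(p_bar - expected)) < 1e-10


def test_stationary_symmetry_for_equivalent_strategies(dyn):
    """With zero cost, zero budget and zero risk the two strategies earn
    identical payoffs in every group, so relabeling C and D is a symmetry
    of the chain and the stationary law is symmetric around Z/2."""
    params = GameParams(Z=40, N=8, M=4, c=0.0, r=0.0)
    p_bar = stationary_distribution(params, IncentivePolicy.none(), dyn)
    assert np.max(np.abs(p_bar - p_bar[::-1])) < 1e-12


def test_stationary_robust_at_strong_selection(baseline_params):
    """The log-space product formula stays normalized at large beta."""
    dyn = DynamicsParams(beta=50.0, mu=0.01)
    p_bar = stationary_distribution(baseline_params, IncentivePolicy.none(), dyn)
    assert np.isfinite(p_bar).all()
    assert p_bar.sum() == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------ chain profile
def test_chain_profile_frame_and_csv(tmp_path, baseline_params, dyn):
    prof = chain_profile(baseline_params, IncentivePolicy.pure_reward(0.01), dyn)
    df = prof.to_frame()
    assert list(df.columns) == [
        "k", "k_over_Z", "f_C", "f_D", "T_plus", "T_minus",
        "T_mu_plus", "T_mu_minus", "G", "p_bar",
    ]
    assert len(df) == baseline_params.Z + 1
    # fitness of an absent strategy is never computed
    assert np.isnan(df.f_C.iloc[0]) and np.isnan(df.f_D.iloc[-1])
    assert df.p_bar.sum() == pytest.approx(1.0, abs=1e-12)
    out = tmp_path / "profile.csv"
    prof.to_csv(out)
    assert out.exists() and out.read_text().startswith("k,")
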