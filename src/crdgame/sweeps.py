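"""Parameter sweeps reproducing the headline analyses as tabular data.

Each sweep runs the analytic pipeline (fitness → transitions → stationary
distribution → group achievement) over a parameter grid and returns a tidy
``pandas.DataFrame``; ``write_outputs`` persists the table as CSV together
with a JSON manifest of every parameter so runs can be reproduced exactly.

The four drivers cover: group achievement versus risk under the competing
incentive schemes; achievement versus the location of the reward→punishment
switching point; gradient/stationary profiles versus the incentive budget;
and the optimal switching point versus the efficiency ratio a/b.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evolution import DynamicsParams, chain_profile
from .game import GameParams, IncentivePolicy
from .metrics import average_group_achievement
from .policy import SwitchingPolicy, optimal_switching_point

__all__ = [
    "sweep_risk",
    "sweep_switch",
    "sweep_delta",
    "sweep_ab",
    "write_outputs",
]

logger = logging.getLogger(__name__)

POLICY_NAMES = ("none", "pure-reward", "pure-punishment", "switching")


def _policies(
    Z: int, delta: float, a: float, b: float, s: float
) -> dict[str, IncentivePolicy]:
    return {
        "none": IncentivePolicy.none(),
        "pure-reward": IncentivePolicy.pure_reward(delta, a, b),
        "pure-punishment": IncentivePolicy.pure_punishment(delta, a, b),
        "switching": SwitchingPolicy(s=s, Z=Z).incentive_policy(delta, a, b),
    }


def _check_grid(grid: Sequence[float], lo: float, hi: float, name: str) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.size == 0 or not np.all(np.isfinite(g)):
        raise ValueError(f"{name} grid must be finite and non-empty")
    if np.any(np.diff(g) < 0):
        raise ValueError(f"{name} grid must be sorted ascending")
    if g.min() < lo or g.max() > hi:
        raise ValueError(f"{name} grid outside [{lo}, {hi}]")
    return g


def sweep_risk(
    params: GameParams,
    dyn: DynamicsParams,
    delta: float,
    risk_grid: Sequence[float] | None = None,
    a: float = 1.0,
    b: float = 1.0,
    s: float | None = None,
) -> pd.DataFrame:
    """Average group achievement versus risk for the four incentive schemes.

    Returns a tidy table with columns ``r``, ``policy`` (none, pure-reward,
    pure-punishment, switching) and ``eta_G``.  The switching curve uses
    the optimal switching point for ``(a, b)`` unless ``s`` is given.
    """
    grid = _check_grid(
        np.linspace(0, 1, 21) if risk_grid is None else risk_grid, 0, 1, "risk"
    )
    if s is None:
        s = optimal_switching_point(params, a, b)
    policies = _policies(params.Z, delta, a, b, s)
    rows = []
    for r in grid:
        p_r = dataclasses.replace(params, r=float(r))
        for name, pol in policies.items():
            eta = average_group_achievement(p_r, pol, dyn).eta_G
            logger.debug("sweep_risk r=%.3f policy=%s eta_G=%.6f", r, name, eta)
            rows.append({"r": float(r), "policy": name, "eta_G": eta})
        logger.info("sweep_risk: r=%.3f done", r)
    return pd.DataFrame(rows)


def sweep_switch(
    params: GameParams,
    dyn: DynamicsParams,
    delta: float,
    s_grid: Sequence[float] | None = None,
    risk_values: Sequence[float] | None = None,
    a: float = 1.0,
    b: float = 1.0,
) -> pd.DataFrame:
    """Average group achievement versus the switching-point location ``s``.

    Columns: ``r``, ``s``, ``eta_G``.  The endpoints are cross-checked
    against the pure policies — ``s = 0`` must reproduce pure punishment
    and ``s = 1`` pure reward bit for bit — and a mismatch raises.
    """
    grid = _check_grid(
        np.linspace(0, 1, 21) if s_grid is None else s_grid, 0, 1, "switching point"
    )
    risks = [params.r] if risk_values is None else list(risk_values)
    rows = []
    for r in risks:
        p_r = dataclasses.replace(params, r=float(r))
        for s in grid:
            pol = SwitchingPolicy(s=float(s), Z=params.Z).incentive_policy(delta, a, b)
            eta = average_group_achievement(p_r, pol, dyn).eta_G
            rows.append({"r": float(r), "s": float(s), "eta_G": eta})
        logger.info("sweep_switch: r=%.3f done", r)
    df = pd.DataFrame(rows)

    # endpoint consistency: the switching rule must degenerate exactly
    for r in risks:
        p_r = dataclasses.replace(params, r=float(r))
        sub = df[df.r == float(r)]
        for s_end, pure in ((0.0, IncentivePolicy.pure_punishment(delta, a, b)),
                            (1.0, IncentivePolicy.pure_reward(delta, a, b))):
            if s_end in set(sub.s):
                eta_pure = average_group_achievement(p_r, pure, dyn).eta_G
                eta_end = float(sub.loc[sub.s == s_end, "eta_G"].iloc[0])
                if eta_end != eta_pure:
                    raise RuntimeError(
                        f"endpoint check failed at s={s_end}, r={r}: "
                        f"{eta_end!r} != pure value {eta_pure!r}"
                    )
    return df


def sweep_delta(
    params: GameParams,
    dyn: DynamicsParams,
    delta_grid: Sequence[float] | None = None,
    a: float = 1.0,
    b: float = 1.0,
) -> pd.DataFrame:
    """Gradient and stationary profiles per budget, under each pure policy.

    Long-format table: one row per (delta, policy, state k) with the full
    chain-profile columns.  At ``delta = 0`` the reward and punishment
    profiles are verified to be identical (the budget is inoperative).
    """
    grid = _check_grid(
        [0.0, 0.005, 0.01, 0.02] if delta_grid is None else delta_grid,
        0, np.inf, "delta",
    )
    frames = []
    for d in grid:
        for name, pol in (
            ("pure-reward", IncentivePolicy.pure_reward(float(d), a, b)),
            ("pure-punishment", IncentivePolicy.pure_punishment(float(d), a, b)),
        ):
            prof = chain_profile(params, pol, dyn).to_frame()
            prof.insert(0, "policy", name)
            prof.insert(0, "delta", float(d))
            frames.append(prof)
        logger.info("sweep_delta: delta=%.4f done", d)
    df = pd.concat(frames, ignore_index=True)

    if 0.0 in grid:
        zero = df[df.delta == 0.0]
        rew = zero[zero.policy == "pure-reward"].drop(columns="policy").reset_index(drop=True)
        pun = zero[zero.policy == "pure-punishment"].drop(columns="policy").reset_index(drop=True)
        if not rew.equals(pun):
            raise RuntimeError("delta=0 profiles differ between reward and punishment")
    return df


def sweep_ab(
    params: GameParams, ratio_grid: Sequence[float]
) -> pd.DataFrame:
    """Optimal switching point ``s*`` along a grid of efficiency ratios a/b.

    The ratio alone determines ``s*`` (the objective is homogeneous in
    ``(a, b)``), so ``a = ratio, b = 1`` is used.
    """
    grid = _check_grid(ratio_grid, 0, np.inf, "a/b ratio")
    rows = []
    for ratio in grid:
        s_star = optimal_switching_point(params, a=float(ratio), b=1.0)
        rows.append({"a_over_b": float(ratio), "s_star": s_star})
    return pd.DataFrame(rows)


def write_outputs(
    df: pd.DataFrame,
    path: str | Path,
    parameters: Mapping[str, object],
    seed: int | None = None,
) -> Path:
    """Write a sweep table as CSV plus a JSON manifest next to it.

    The manifest records every parameter, the package version and any seed,
    so the run can be reproduced exactly; it is written to
    ``<path>.manifest.json``.  Returns the CSV path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest = {
        "tool": "crdgame",
        "version": __version__,
        "parameters": dict(parameters),
        "seed": seed,
        "rows": int(len(df)),
        "columns": list(df.columns),
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
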