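"""Exploitation-preference sweeps and the hawk/dove cooperation cut-off.

How strongly Ego prefers to exploit Alter — to play the hostile action
while receiving a friendly one — decides whether cooperation minimizes
his risk.  Sweeping that preference traces each policy's risk curve:
the cooperative contract's risk rises with the exploitation preference
while the hostile forced policy's risk falls, so the two curves cross
at most once.  Below the crossing the agent cooperates (dove-like);
above it he does not (hawk-like); exactly at the crossing the two
policies carry equal risk, there is no clear best policy, and the
stress flag raises.

Sweeps run in two parameter spaces:

* ``exploitation_reward`` — set the reward of the exploitation states
  and re-derive the prior by linear normalization (the mechanism of
  "raise the reward for exploitation, keep all other rewards fixed");
* ``exploitation_probability`` — set each exploitation state's prior
  probability directly and rescale the remaining states
  proportionally, for plotting against a probability axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .decision import evaluate_all
from .game import GameSpec, RewardMatrix, encode_preferences
from .information import DiscreteDistribution

__all__ = [
    "SweepResult",
    "CutoffEstimate",
    "exploitation_states",
    "sweep_exploitation",
    "find_cutoff",
    "classify_agent",
    "DEFAULT_FLOOR",
]

from .game import DEFAULT_FLOOR

#: |risk_a - risk_b| at the reported cut-off must be below this
CUTOFF_RESIDUAL_BITS = 1e-9
#: bisection stops when the parameter bracket is narrower than this
CUTOFF_PARAM_TOL = 1e-10


@dataclass(frozen=True)
class SweepResult:
    """Per-policy risk curves over a grid of exploitation preferences."""

    parameter_name: str
    grid: tuple
    curves: dict  # policy name -> tuple of risks (bits), len == len(grid)
    cutoff: Optional["CutoffEstimate"] = None

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise ValueError("grid is empty")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        for name, curve in self.curves.items():
            if len(curve) != g.size:
                raise ValueError(f"curve {name!r} length != grid length")


@dataclass(frozen=True)
class CutoffEstimate:
    """The exploitation preference at which two policy risks coincide."""

    parameter_value: float
    exploit_probability: float  # per exploitation state, at the cut-off
    policy_pair: tuple
    residual: float  # |risk difference| at the estimate, bits

    def __post_init__(self):
        if not self.residual < CUTOFF_RESIDUAL_BITS:
            raise ValueError(
                f"cut-off residual {self.residual:g} bits exceeds "
                f"{CUTOFF_RESIDUAL_BITS:g}")


def exploitation_states(game: GameSpec, hostile_ego_action: Optional[str] = None
                        ) -> tuple:
    """Joint states where Ego exploits: hostile ego x friendly alter.

    The hostile ego action defaults to the one banned by the game's
    contract policy; the friendly alter actions are those the contract
    permits.  Pass *hostile_ego_action* to override.
    """
    contract = next((p for p in game.policies if p.kind == "contract"), None)
    if hostile_ego_action is None:
        if contract is None or len(contract.banned_ego_actions) != 1:
            raise ValueError(
                "cannot infer the hostile ego action: no contract policy "
                "banning exactly one ego action; pass hostile_ego_action")
        hostile_ego_action = next(iter(contract.banned_ego_actions))
    if hostile_ego_action not in game.space.ego_actions:
        raise ValueError(f"unknown ego action {hostile_ego_action!r}")
    banned_alter = contract.banned_alter_actions if contract else frozenset()
    friendly_alter = [a for a in game.space.alter_actions
                      if a not in banned_alter]
    if not friendly_alter:
        raise ValueError("no friendly alter actions")
    return tuple((hostile_ego_action, a) for a in friendly_alter)


def _game_at(game: GameSpec, value: float, parameter_name: str,
             exploit: tuple, floor: float) -> GameSpec:
    """Rebuild the game with the exploitation preference set to *value*."""
    if parameter_name == "exploitation_reward":
        if value < 0:
            raise ValueError("exploitation reward must be >= 0")
        vals = dict(game.rewards.values)
        for s in exploit:
            vals[s] = value
        if all(v == 0 for v in vals.values()):
            raise ValueError("grid value makes all rewards zero")
        return game.with_rewards(RewardMatrix(vals), floor)
    elif parameter_name == "exploitation_probability":
        k = len(exploit)
        if not (0.0 <= value * k < 1.0):
            raise ValueError(
                f"per-state exploitation probability {value} infeasible for "
                f"{k} exploitation states")
        prior = game.prior.as_dict()
        rest = [s for s in game.prior.labels if s not in exploit]
        rest_mass = sum(prior[s] for s in rest)
        if rest_mass <= 0:
            raise ValueError("prior puts no mass outside exploitation states")
        scale = (1.0 - value * k) / rest_mass
        probs = [value if s in exploit else prior[s] * scale
                 for s in game.prior.labels]
        return game.with_prior(
            DiscreteDistribution(game.prior.labels, probs, renormalize=True))
    raise ValueError(f"unknown parameter_name {parameter_name!r}")


def sweep_exploitation(game: GameSpec, grid: Sequence[float],
                       parameter_name: str = "exploitation_reward", *,
                       hostile_ego_action: Optional[str] = None,
                       floor: float = DEFAULT_FLOOR) -> SweepResult:
    """Trace every policy's risk across a grid of exploitation preferences."""
    exploit = exploitation_states(game, hostile_ego_action)
    grid = tuple(float(v) for v in grid)
    curves: dict = {p.name: [] for p in game.policies}
    for value in grid:
        report = evaluate_all(_game_at(game, value, parameter_name,
                                       exploit, floor))
        for ev in report.evaluations:
            curves[ev.policy_name].append(ev.risk_bits)
    return SweepResult(parameter_name=parameter_name, grid=grid,
                       curves={k: tuple(v) for k, v in curves.items()})


def find_cutoff(game: GameSpec, policy_a: str, policy_b: str,
                bracket: tuple, parameter_name: str = "exploitation_reward", *,
                hostile_ego_action: Optional[str] = None,
                floor: float = DEFAULT_FLOOR) -> CutoffEstimate:
    """Locate the parameter value where two policies' risks are equal.

    Bisection on the (monotone) risk difference; the bracket endpoints
    must straddle the crossing.  Reports both the parameter value and
    the per-state exploitation probability it implies, so reward-space
    cut-offs can be read on a probability axis.
    """
    exploit = exploitation_states(game, hostile_ego_action)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"bracket must satisfy lo < hi, got {bracket!r}")

    def diff(value: float) -> float:
        g = _game_at(game, value, parameter_name, exploit, floor)
        report = evaluate_all(g)
        return (report.evaluation(policy_a).risk_bits
                - report.evaluation(policy_b).risk_bits)

    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo == 0.0 and d_hi == 0.0:
        raise ValueError(
            f"{policy_a!r} and {policy_b!r} have equal risk across the whole "
            f"bracket {bracket!r}: no crossing to locate")
    if d_lo == 0.0:
        root = lo
    elif d_hi == 0.0:
        root = hi
    elif d_lo * d_hi > 0:
        raise ValueError(
            f"risk difference of {policy_a!r} and {policy_b!r} does not "
            f"change sign over {bracket!r} "
            f"({d_lo:+.6g} to {d_hi:+.6g} bits); widen the bracket")
    else:
        while hi - lo > CUTOFF_PARAM_TOL:
            mid = 0.5 * (lo + hi)
            d_mid = diff(mid)
            if d_mid == 0.0:
                lo = hi = mid
                break
            if (d_mid > 0) == (d_lo > 0):
                lo, d_lo = mid, d_mid
            else:
                hi = mid
        root = 0.5 * (lo + hi)

    g_star = _game_at(game, root, parameter_name, exploit, floor)
    p_star = sum(g_star.prior.prob(s) for s in exploit) / len(exploit)
    return CutoffEstimate(parameter_value=root, exploit_probability=p_star,
                          policy_pair=(policy_a, policy_b),
                          residual=abs(diff(root)))


def classify_agent(game: GameSpec, cutoff: CutoffEstimate, *,
                   hostile_ego_action: Optional[str] = None,
                   tolerance: float = 1e-9) -> str:
    """Classify the agent as ``"dove"``, ``"hawk"`` or ``"borderline"``.

    Compares the game's current per-state exploitation probability with
    the cut-off probability: below it, cooperation minimizes risk and
    the agent cooperates (dove); above it, it does not (hawk); within
    *tolerance* the risks tie and the classification is borderline —
    the stress condition.
    """
    exploit = exploitation_states(game, hostile_ego_action)
    p = sum(game.prior.prob(s) for s in exploit) / len(exploit)
    if abs(p - cutoff.exploit_probability) <= tolerance:
        return "borderline"
    return "dove" if p < cutoff.exploit_probability else "hawk"
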