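"""Two-agent game model: joint states, reward-derived preferences, policies.

A game couples an Ego agent and an Alter agent.  Each picks one action;
the joint state is the ordered pair ``(ego_action, alter_action)``.
Ego's preferences over joint states are encoded as a prior probability
distribution derived from a non-negative reward matrix by linear
normalization, so raising one state's reward while holding the others
fixed monotonically raises that state's prior probability.

Two kinds of policy are modelled:

* ``forced_action`` — Ego commits to one of his own actions; the
  attainable states are that row of the matrix, distributed according
  to Ego's model of Alter (uniform when Ego knows nothing about Alter).
* ``contract`` — an enforceable agreement banning designated actions
  for *both* agents; the attainable states are uniform over the joint
  states that touch no banned action.  This is the cooperative device
  that makes hostile commitments unreachable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .information import DiscreteDistribution

__all__ = [
    "JointStateSpace",
    "RewardMatrix",
    "PolicySpec",
    "GameSpec",
    "encode_preferences",
    "apply_contract",
    "build_policy_posterior",
    "load_game",
    "save_game",
    "game_to_config",
    "GameConfigError",
    "DEFAULT_FLOOR",
]

#: default reward floor, as a fraction of the maximum reward; keeps
#: zero-reward ("sucker") states at tiny-but-finite prior probability so
#: policies that can reach them get large finite risks, not infinities
DEFAULT_FLOOR = 1e-6


@dataclass(frozen=True)
class JointStateSpace:
    """Cartesian product of the two agents' action sets, ego-major order."""

    ego_actions: tuple
    alter_actions: tuple

    def __init__(self, ego_actions: Sequence[str], alter_actions: Sequence[str]):
        ego = tuple(ego_actions)
        alter = tuple(alter_actions)
        for name, acts in (("ego", ego), ("alter", alter)):
            if len(acts) == 0:
                raise ValueError(f"{name} action set is empty")
            if len(set(acts)) != len(acts):
                raise ValueError(f"duplicate {name} action labels: {acts!r}")
        object.__setattr__(self, "ego_actions", ego)
        object.__setattr__(self, "alter_actions", alter)

    @property
    def states(self) -> tuple:
        """All joint states (ego, alter), row-major with ego first."""
        return tuple((e, a) for e in self.ego_actions for a in self.alter_actions)

    def __len__(self) -> int:
        return len(self.ego_actions) * len(self.alter_actions)


@dataclass(frozen=True)
class RewardMatrix:
    """Non-negative rewards over joint states (arbitrary utility units)."""

    values: Mapping[tuple, float]

    def __init__(self, values: Mapping[tuple, float]):
        vals = {tuple(k): float(v) for k, v in values.items()}
        if not vals:
            raise ValueError("reward matrix is empty")
        if any(v < 0 for v in vals.values()):
            raise ValueError("rewards must be non-negative")
        if all(v == 0 for v in vals.values()):
            raise ValueError("at least one reward must be positive")
        object.__setattr__(self, "values", vals)

    def reward(self, state: tuple) -> float:
        return self.values[tuple(state)]

    def max_reward(self) -> float:
        return max(self.values.values())


@dataclass(frozen=True)
class PolicySpec:
    """One entry of the policy repertoire.

    Either Ego forces one of his own actions (``kind="forced_action"``)
    or both agents sign a contract banning actions (``kind="contract"``).
    """

    name: str
    kind: Literal["forced_action", "contract"]
    forced_ego_action: Optional[str] = None
    banned_ego_actions: frozenset = frozenset()
    banned_alter_actions: frozenset = frozenset()

    def __post_init__(self):
        if self.kind == "forced_action":
            if self.forced_ego_action is None:
                raise ValueError(
                    f"policy {self.name!r}: forced_action requires forced_ego_action")
            if self.banned_ego_actions or self.banned_alter_actions:
                raise ValueError(
                    f"policy {self.name!r}: forced_action takes no bans")
        elif self.kind == "contract":
            if self.forced_ego_action is not None:
                raise ValueError(
                    f"policy {self.name!r}: contract takes no forced action")
            object.__setattr__(self, "banned_ego_actions",
                               frozenset(self.banned_ego_actions))
            object.__setattr__(self, "banned_alter_actions",
                               frozenset(self.banned_alter_actions))
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown policy kind {self.kind!r}")

    def validate_against(self, space: JointStateSpace) -> None:
        """Check all referenced actions exist and a contract permits >= 1 state."""
        if self.kind == "forced_action":
            if self.forced_ego_action not in space.ego_actions:
                raise ValueError(
                    f"policy {self.name!r}: unknown ego action "
                    f"{self.forced_ego_action!r}")
        else:
            bad_e = self.banned_ego_actions - set(space.ego_actions)
            bad_a = self.banned_alter_actions - set(space.alter_actions)
            if bad_e or bad_a:
                raise ValueError(
                    f"policy {self.name!r}: unknown banned actions "
                    f"{sorted(bad_e | bad_a)!r}")
            apply_contract(space, self.banned_ego_actions,
                           self.banned_alter_actions)  # raises if empty


@dataclass(frozen=True)
class GameSpec:
    """A complete two-agent decision problem from Ego's point of view."""

    space: JointStateSpace
    rewards: RewardMatrix
    prior: DiscreteDistribution
    policies: tuple
    opponent_model: DiscreteDistribution
    agent_id: str = "Ego"

    def __post_init__(self):
        object.__setattr__(self, "policies", tuple(self.policies))
        if self.prior.labels != self.space.states:
            raise ValueError("prior labels must equal the joint state space, "
                             "in ego-major order")
        if self.opponent_model.labels != self.space.alter_actions:
            raise ValueError("opponent model labels must equal the alter "
                             "action set")
        names = [p.name for p in self.policies]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate policy names: {names!r}")
        for p in self.policies:
            p.validate_against(self.space)

    def policy(self, name: str) -> PolicySpec:
        for p in self.policies:
            if p.name == name:
                return p
        raise KeyError(f"no policy named {name!r}")

    def with_rewards(self, rewards: RewardMatrix, floor: float) -> "GameSpec":
        """New game with the prior re-derived from *rewards*."""
        return replace(self, rewards=rewards,
                       prior=encode_preferences(rewards, floor,
                                                order=self.space.states))

    def with_prior(self, prior: DiscreteDistribution) -> "GameSpec":
        return replace(self, prior=prior)


def encode_preferences(rewards: RewardMatrix, floor: float = 0.0, *,
                       order: Optional[Sequence[tuple]] = None
                       ) -> DiscreteDistribution:
    """Encode a reward matrix as a preference prior by linear normalization.

    ``prior(s) proportional to max(reward(s), floor * max_reward)``.  The
    linear map (rather than e.g. a softmax) makes the prior
    scale-invariant in the rewards and strictly monotone in each single
    reward, so "raising the reward for one outcome" cleanly raises that
    outcome's prior probability.

    Parameters
    ----------
    rewards
        Non-negative rewards per joint state.
    floor
        Fraction of the maximum reward used as a lower bound, so
        zero-reward states keep a tiny finite probability.  ``0``
        disables the floor.
    order
        State order for the output distribution; defaults to the reward
        matrix's own key order.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    states = tuple(order) if order is not None else tuple(rewards.values)
    lo = floor * rewards.max_reward()
    weights = [max(rewards.reward(s), lo) for s in states]
    if sum(weights) <= 0:
        raise ValueError("all rewards zero with floor 0: prior undefined")
    return DiscreteDistribution(states, weights, renormalize=True)


def apply_contract(space: JointStateSpace, banned_ego, banned_alter) -> tuple:
    """Joint states that touch no banned action, order preserved."""
    banned_ego = set(banned_ego)
    banned_alter = set(banned_alter)
    if not banned_ego <= set(space.ego_actions):
        raise ValueError(f"banned ego actions {sorted(banned_ego)!r} not all "
                         "in the ego action set")
    if not banned_alter <= set(space.alter_actions):
        raise ValueError(f"banned alter actions {sorted(banned_alter)!r} not "
                         "all in the alter action set")
    permitted = tuple((e, a) for (e, a) in space.states
                      if e not in banned_ego and a not in banned_alter)
    if not permitted:
        raise ValueError("contract bans every joint state")
    return permitted


def build_policy_posterior(game: GameSpec, policy: PolicySpec
                           ) -> DiscreteDistribution:
    """Attainable-state distribution P(S|pi) for one policy.

    Forced action: mass on that ego row, split across alter actions per
    the opponent model (uniform when Ego has no model of Alter).
    Contract: uniform over all permitted joint states — the
    maximum-entropy reading of "any non-banned combination may occur".
    """
    policy.validate_against(game.space)
    states = game.space.states
    if policy.kind == "forced_action":
        om = game.opponent_model.as_dict()
        probs = [om[a] if e == policy.forced_ego_action else 0.0
                 for (e, a) in states]
    else:
        permitted = set(apply_contract(game.space, policy.banned_ego_actions,
                                       policy.banned_alter_actions))
        w = 1.0 / len(permitted)
        probs = [w if s in permitted else 0.0 for s in states]
    return DiscreteDistribution(states, probs, renormalize=True)


# ---------------------------------------------------------------------------
# Config document handling
# ---------------------------------------------------------------------------

class GameConfigError(ValueError):
    """Raised when a game config document is structurally invalid."""


class _PolicyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    kind: Literal["forced_action", "contract"]
    forced_ego_action: Optional[str] = None
    banned_ego_actions: list[str] = []
    banned_alter_actions: list[str] = []


class _GameConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    agents: dict[Literal["ego", "alter"], list[str]]
    rewards: dict[str, float]
    policies: list[_PolicyConfig]
    prior: Optional[dict[str, float]] = None
    opponent_model: Optional[dict[str, float]] = None
    floor: float = DEFAULT_FLOOR
    agent_id: str = "Ego"

    @model_validator(mode="after")
    def _nonempty(self):
        if "ego" not in self.agents or "alter" not in self.agents:
            raise ValueError("agents must define both 'ego' and 'alter'")
        return self


def _state_key(state: tuple) -> str:
    return f"{state[0]},{state[1]}"


def _parse_state_key(key: str, space: JointStateSpace) -> tuple:
    parts = tuple(p.strip() for p in key.split(","))
    if len(parts) != 2:
        raise GameConfigError(
            f"rewards: key {key!r} is not of the form 'ego_action,alter_action'")
    if parts not in space.states:
        raise GameConfigError(f"rewards: unknown joint state {key!r}")
    return parts


def load_game(source) -> GameSpec:
    """Construct a :class:`GameSpec` from a config document.

    *source* may be a path to a JSON file, a JSON string, or an
    already-parsed mapping.  The prior is derived from the rewards via
    :func:`encode_preferences` unless the document supplies an explicit
    ``prior``, which is then taken verbatim.
    """
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    elif isinstance(source, (str, Path)):
        p = Path(source)
        if not p.exists():
            raise GameConfigError(f"no such game config file: {source}")
        doc = json.loads(p.read_text())
    else:
        doc = source
    try:
        cfg = _GameConfig.model_validate(doc)
    except ValidationError as exc:
        paths = "; ".join(
            "/".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise GameConfigError(f"invalid game config: {paths}") from exc

    space = JointStateSpace(cfg.agents["ego"], cfg.agents["alter"])
    reward_vals = {}
    for key, val in cfg.rewards.items():
        reward_vals[_parse_state_key(key, space)] = val
    missing = set(space.states) - set(reward_vals)
    if missing:
        raise GameConfigError(
            f"rewards: missing entries for states {sorted(missing)!r}")
    rewards = RewardMatrix(reward_vals)

    if cfg.prior is not None:
        prior_vals = {}
        for key, val in cfg.prior.items():
            prior_vals[_parse_state_key(key, space)] = val
        missing = set(space.states) - set(prior_vals)
        if missing:
            raise GameConfigError(
                f"prior: missing entries for states {sorted(missing)!r}")
        prior = DiscreteDistribution(space.states,
                                     [prior_vals[s] for s in space.states])
    else:
        prior = encode_preferences(rewards, cfg.floor, order=space.states)

    if cfg.opponent_model is not None:
        unknown = set(cfg.opponent_model) - set(space.alter_actions)
        if unknown:
            raise GameConfigError(
                f"opponent_model: unknown alter actions {sorted(unknown)!r}")
        om = DiscreteDistribution(
            space.alter_actions,
            [cfg.opponent_model.get(a, 0.0) for a in space.alter_actions])
    else:
        om = DiscreteDistribution(
            space.alter_actions,
            [1.0 / len(space.alter_actions)] * len(space.alter_actions))

    policies = []
    for pc in cfg.policies:
        try:
            spec = PolicySpec(
                name=pc.name, kind=pc.kind,
                forced_ego_action=pc.forced_ego_action,
                banned_ego_actions=frozenset(pc.banned_ego_actions),
                banned_alter_actions=frozenset(pc.banned_alter_actions))
            spec.validate_against(space)
        except ValueError as exc:
            raise GameConfigError(f"policies/{pc.name}: {exc}") from exc
        policies.append(spec)

    try:
        return GameSpec(space=space, rewards=rewards, prior=prior,
                        policies=tuple(policies), opponent_model=om,
                        agent_id=cfg.agent_id)
    except ValueError as exc:
        raise GameConfigError(str(exc)) from exc


def game_to_config(game: GameSpec, *, floor: float = DEFAULT_FLOOR,
                   explicit_prior: bool = True) -> dict:
    """Serialize a game back into the config-document form.

    The prior is written out explicitly by default so that
    load -> save -> load is bit-exact regardless of the floor the prior
    was originally derived with.
    """
    doc = {
        "agents": {"ego": list(game.space.ego_actions),
                   "alter": list(game.space.alter_actions)},
        "rewards": {_state_key(s): game.rewards.reward(s)
                    for s in game.space.states},
        "policies": [],
        "opponent_model": dict(zip(game.space.alter_actions,
                                   game.opponent_model.probs)),
        "floor": floor,
        "agent_id": game.agent_id,
    }
    if explicit_prior:
        doc["prior"] = {_state_key(s): p
                        for s, p in zip(game.prior.labels, game.prior.probs)}
    for p in game.policies:
        entry = {"name": p.name, "kind": p.kind}
        if p.kind == "forced_action":
            entry["forced_ego_action"] = p.forced_ego_action
        else:
            entry["banned_ego_actions"] = sorted(p.banned_ego_actions)
            entry["banned_alter_actions"] = sorted(p.banned_alter_actions)
        doc["policies"].append(entry)
    return doc


def save_game(game: GameSpec, path, **kwargs) -> None:
    """Write a game config document as canonical JSON."""
    doc = game_to_config(game, **kwargs)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
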