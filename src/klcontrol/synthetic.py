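"""Generators for every input the analysis needs; no downloads required.

Three families of inputs:

* the 9-state Ego–Alter game with a prisoner's-dilemma preference
  structure (two friendly and one hostile action per agent, canonical
  payoffs T=5 > R=3 > P=1 > S=0), together with the four-policy
  repertoire including the cooperative contract;
* Gaussian goal/attainable belief pairs for the continuous-state
  illustration of policy risk;
* seeded random games with a one-parameter control of preference
  peakedness, used as a test surface for oracle cross-checks.

Every generator is a pure function of its arguments (and seed), so
identical calls produce identical objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import evaluate_all
from .game import (DEFAULT_FLOOR, GameSpec, JointStateSpace, PolicySpec,
                   RewardMatrix, encode_preferences)
from .information import DiscreteDistribution, GaussianBelief

__all__ = [
    "FixtureBundle",
    "make_pd_fixture",
    "make_gaussian_fixture",
    "generate_random_game",
    "make_restriction_pair",
    "PD_REWARDS",
]

#: canonical prisoner's-dilemma payoffs: temptation, reward, punishment, sucker
PD_REWARDS = {"T": 5.0, "R": 3.0, "P": 1.0, "S": 0.0}


@dataclass(frozen=True)
class FixtureBundle:
    """A ready-to-evaluate game plus notes on where its numbers come from."""

    game: GameSpec
    description: str
    provenance_notes: str

    def __post_init__(self):
        if not self.provenance_notes.strip():
            raise ValueError("provenance_notes must be non-empty")


def make_pd_fixture(floor: float = DEFAULT_FLOOR) -> FixtureBundle:
    """The 9-state prisoner's-dilemma-structured Ego–Alter game.

    Actions E1/E2 (A1/A2) are friendly, E3 (A3) hostile.  Ego's rewards:
    T=5 for exploiting (E3 with a friendly A1/A2), R=3 for mutual
    friendliness, P=1 for mutual hostility, S=0 for being exploited.
    With ``floor=0`` the prior puts 5/23 ≈ 0.217 on each exploitation
    state; the default tiny floor keeps the zero-reward states at a
    finite sliver so no forced policy has literally infinite risk.

    The repertoire is Policy 1/2/3 (force E1/E2/E3) plus the Cooperate
    contract banning the hostile action for both agents.
    """
    space = JointStateSpace(("E1", "E2", "E3"), ("A1", "A2", "A3"))
    T, R, P, S = (PD_REWARDS[k] for k in "TRPS")
    rewards = RewardMatrix({
        ("E1", "A1"): R, ("E1", "A2"): R, ("E1", "A3"): S,
        ("E2", "A1"): R, ("E2", "A2"): R, ("E2", "A3"): S,
        ("E3", "A1"): T, ("E3", "A2"): T, ("E3", "A3"): P,
    })
    policies = (
        PolicySpec("Policy 1", "forced_action", forced_ego_action="E1"),
        PolicySpec("Policy 2", "forced_action", forced_ego_action="E2"),
        PolicySpec("Policy 3", "forced_action", forced_ego_action="E3"),
        PolicySpec("Cooperate", "contract",
                   banned_ego_actions=frozenset({"E3"}),
                   banned_alter_actions=frozenset({"A3"})),
    )
    game = GameSpec(
        space=space, rewards=rewards,
        prior=encode_preferences(rewards, floor, order=space.states),
        policies=policies,
        opponent_model=DiscreteDistribution(space.alter_actions,
                                            [1 / 3, 1 / 3, 1 / 3]),
        agent_id="Ego")
    return FixtureBundle(
        game=game,
        description="9-state Ego-Alter game with prisoner's-dilemma "
                    "preferences and a cooperative contract policy",
        provenance_notes=(
            "Reconstruction, not published data: the qualitative structure "
            "(3x3 joint states, exploitation preferred, four policies, "
            "contract banning E3/A3, uniform opponent model) is fixed by the "
            "scenario; the numeric rewards are the canonical prisoner's-"
            "dilemma payoffs T=5, R=3, P=1, S=0, chosen because linear "
            "normalization then gives each exploitation state prior "
            "probability 5/23 = 0.2174, consistent with the scenario's "
            "stated low-to-medium exploitation preference of about 0.22. "
            f"floor={floor!r} applied to zero-reward states."))


def make_gaussian_fixture(goal_mean: float = 3.0, goal_sd: float = 1.0,
                          attainable_mean: float = 5.3,
                          attainable_sd: float = 1.0
                          ) -> tuple[GaussianBelief, GaussianBelief]:
    """Goal and attainable Gaussian beliefs for the continuous example.

    Defaults place the preferred state at 3.0 and the attainable mean at
    5.3 with unit spread; with equal sds the policy risk is quadratic in
    the distance between the two means.  Returns ``(goal, attainable)``.
    """
    return (GaussianBelief(goal_mean, goal_sd),
            GaussianBelief(attainable_mean, attainable_sd))


def generate_random_game(seed: int, n_ego_actions: int = 3,
                         n_alter_actions: int = 3,
                         reward_concentration: float = 1.0,
                         floor: float = DEFAULT_FLOOR) -> GameSpec:
    """A seeded random game for property tests and oracle cross-checks.

    Rewards are i.i.d. Gamma(concentration, 1/concentration) draws
    (mean 1): small concentrations give peaked preference priors, large
    ones nearly uniform.  The repertoire is one forced policy per ego
    action plus a contract banning the ego action and the alter action
    with the lowest total reward.
    """
    if n_ego_actions < 2 or n_alter_actions < 2:
        raise ValueError("need at least 2 actions per agent")
    if not reward_concentration > 0:
        raise ValueError("reward_concentration must be > 0")
    rng = np.random.default_rng(seed)
    ego = tuple(f"E{i + 1}" for i in range(n_ego_actions))
    alter = tuple(f"A{j + 1}" for j in range(n_alter_actions))
    space = JointStateSpace(ego, alter)
    draws = rng.gamma(shape=reward_concentration,
                      scale=1.0 / reward_concentration,
                      size=(n_ego_actions, n_alter_actions))
    rewards = RewardMatrix({(e, a): float(draws[i, j])
                            for i, e in enumerate(ego)
                            for j, a in enumerate(alter)})
    worst_ego = ego[int(np.argmin(draws.sum(axis=1)))]
    worst_alter = alter[int(np.argmin(draws.sum(axis=0)))]
    policies = tuple(PolicySpec(f"Force {e}", "forced_action",
                                forced_ego_action=e) for e in ego)
    policies += (PolicySpec("Contract", "contract",
                            banned_ego_actions=frozenset({worst_ego}),
                            banned_alter_actions=frozenset({worst_alter})),)
    return GameSpec(
        space=space, rewards=rewards,
        prior=encode_preferences(rewards, floor, order=space.states),
        policies=policies,
        opponent_model=DiscreteDistribution(
            alter, [1.0 / n_alter_actions] * n_alter_actions),
        agent_id="Ego")


def _simple_game(rewards: dict, contract_bans_alter: frozenset,
                 floor: float) -> GameSpec:
    ego = tuple(sorted({e for e, _ in rewards}))
    alter = tuple(sorted({a for _, a in rewards}))
    space = JointStateSpace(ego, alter)
    rm = RewardMatrix(rewards)
    policies = tuple(PolicySpec(f"Force {e}", "forced_action",
                                forced_ego_action=e) for e in ego)
    policies += (PolicySpec("Contract", "contract",
                            banned_alter_actions=contract_bans_alter),)
    return GameSpec(
        space=space, rewards=rm,
        prior=encode_preferences(rm, floor, order=space.states),
        policies=policies,
        opponent_model=DiscreteDistribution(alter,
                                            [1.0 / len(alter)] * len(alter)),
        agent_id="Ego")


def make_restriction_pair(floor: float = DEFAULT_FLOOR
                          ) -> tuple[FixtureBundle, FixtureBundle]:
    """Two games showing that a restriction can cut or raise the risk.

    Game A: one alter action leads to states that are both likely (the
    opponent model is uniform) and strongly dispreferred.  A contract
    banning it buys a large expected-utility gain that outweighs the
    lost options, so the contract beats every unrestricted policy.

    Game B: the prior concentrates on a single desirable state.  A
    contract banning that state's alter action forfeits the best
    outcome for a modest gain in kept-open options, so the best
    unrestricted (forced) policy beats the contract.

    Both claims are verified at construction time by evaluating the
    repertoires; a violation raises ``RuntimeError``.
    """
    # A: A3 is aversive (reward 0.01 vs 3.0 elsewhere); Contract bans A3.
    rewards_a = {(e, a): (0.01 if a == "A3" else 3.0)
                 for e in ("E1", "E2", "E3") for a in ("A1", "A2", "A3")}
    game_a = _simple_game(rewards_a, frozenset({"A3"}), floor)

    # B: (E1, A1) is highly rewarded; Contract bans A1, losing it.
    rewards_b = {(e, a): (10.0 if (e, a) == ("E1", "A1") else 1.0)
                 for e in ("E1", "E2", "E3") for a in ("A1", "A2", "A3")}
    game_b = _simple_game(rewards_b, frozenset({"A1"}), floor)

    for game, should_help in ((game_a, True), (game_b, False)):
        report = evaluate_all(game)
        contract_risk = report.evaluation("Contract").risk_bits
        best_forced = min(ev.risk_bits for ev in report.evaluations
                          if ev.policy_name != "Contract")
        helped = contract_risk < best_forced
        if helped != should_help:
            raise RuntimeError("restriction-pair construction invariant "
                               "broken; fixture no longer demonstrates its "
                               "intended direction")

    bundle_a = FixtureBundle(
        game=game_a,
        description="restriction lowers risk: contract bans a likely, "
                    "highly aversive alter action",
        provenance_notes="Constructed example; rewards 3.0 on friendly "
                         "columns, 0.01 on the aversive one. Verified at "
                         "build time that the contract's risk is below "
                         "every forced policy's.")
    bundle_b = FixtureBundle(
        game=game_b,
        description="restriction raises risk: contract bans the alter "
                    "action behind a moderately likely, desirable state",
        provenance_notes="Constructed example; reward 10.0 on one state, "
                         "1.0 elsewhere. Verified at build time that the "
                         "best forced policy's risk is below the "
                         "contract's.")
    return bundle_a, bundle_b
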