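"""Policy evaluation and selection by minimal KL risk.

Every policy in a game's repertoire is scored by the KL divergence
between its attainable-state distribution and the agent's preference
prior, together with the expected-utility and entropy components of
that risk.  The agent selects the policy with minimal risk.  When two
or more policies are tied at the minimum there is no clear best policy;
that tie — not any broken version of it — is the model's stress
condition, so ties are surfaced, never silently resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .game import GameSpec, PolicySpec, build_policy_posterior
from .information import decompose_risk

__all__ = [
    "PolicyEvaluation",
    "DecisionReport",
    "evaluate_policy",
    "evaluate_all",
    "detect_stress",
    "TIE_TOLERANCE_BITS",
]

#: two risks closer than this (in bits) are considered equal; guards the
#: exact-equality tie concept against float noise
TIE_TOLERANCE_BITS = 1e-9


@dataclass(frozen=True)
class PolicyEvaluation:
    """Risk of one policy in bits, with its decomposition.

    ``risk_bits == -expected_utility_term - entropy_term`` whenever the
    risk is finite; an infinite risk means the policy can reach a state
    the prior assigns zero probability.
    """

    policy_name: str
    risk_bits: float
    expected_utility_term: float
    entropy_term: float

    def __post_init__(self):
        if math.isfinite(self.risk_bits):
            resid = abs(self.risk_bits
                        - (-self.expected_utility_term - self.entropy_term))
            if resid > 1e-9:
                raise ValueError(
                    f"decomposition identity violated by {resid:g} bits")


@dataclass(frozen=True)
class DecisionReport:
    """Outcome of evaluating a full policy repertoire.

    ``selected`` is the unique minimal-risk policy, or ``None`` when
    ``tie`` is set; ``tie_members`` lists every policy within tolerance
    of the minimum (two or more when tied).
    """

    evaluations: tuple
    selected: Optional[str]
    tie: bool
    tie_members: tuple = field(default=())

    def evaluation(self, name: str) -> PolicyEvaluation:
        for ev in self.evaluations:
            if ev.policy_name == name:
                return ev
        raise KeyError(f"no evaluation for policy {name!r}")

    @property
    def min_risk_bits(self) -> float:
        return min(ev.risk_bits for ev in self.evaluations)


def evaluate_policy(game: GameSpec, policy: PolicySpec) -> PolicyEvaluation:
    """Risk and decomposition of a single policy against the game's prior."""
    posterior = build_policy_posterior(game, policy)
    eu, ent, risk = decompose_risk(posterior, game.prior)
    return PolicyEvaluation(policy_name=policy.name, risk_bits=risk,
                            expected_utility_term=eu, entropy_term=ent)


def evaluate_all(game: GameSpec) -> DecisionReport:
    """Evaluate the whole repertoire and pick the minimal-risk policy.

    Infinite-risk policies appear in the report but are never selected
    unless every policy is infinite — in which case all are tied and
    nothing is selected.  Deterministic: depends only on the game, not
    on policy order (ties are reported by repertoire order).
    """
    if not game.policies:
        raise ValueError("game has no policies to evaluate")
    evals = tuple(evaluate_policy(game, p) for p in game.policies)

    finite = [ev for ev in evals if math.isfinite(ev.risk_bits)]
    if finite:
        best = min(ev.risk_bits for ev in finite)
        members = tuple(ev.policy_name for ev in evals
                        if math.isfinite(ev.risk_bits)
                        and ev.risk_bits - best <= TIE_TOLERANCE_BITS)
    else:
        members = tuple(ev.policy_name for ev in evals)
    tie = len(members) >= 2
    selected = None if tie or not finite else members[0]
    return DecisionReport(evaluations=evals, selected=selected, tie=tie,
                          tie_members=members if tie else members[:1])


def detect_stress(report: DecisionReport) -> tuple[bool, str]:
    """Flag the no-clear-best-policy condition.

    Returns ``(stressed, explanation)``.  Stress is exactly the tie
    among minimal-risk policies: the agent cannot resolve which policy
    minimizes expected surprise.
    """
    if report.tie:
        names = ", ".join(report.tie_members)
        return True, (f"no clear best policy: {names} share the minimal "
                      "risk within tolerance")
    return False, (f"clear best policy: {report.selected} uniquely "
                   "minimizes risk")
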