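"""Exact information-theoretic primitives, reported in bits.

The quantities here follow the KL-control view of decision making: an
agent's goals are a probability distribution over states (prior
preferences), a policy induces a distribution over attainable states,
and the *risk* of the policy is the Kullback-Leibler divergence from the
attainable-state distribution to the preference prior — its expected
future surprise.  The divergence decomposes as

    risk = cross_entropy - entropy
         = -sum_s P(s|pi) log2 P(s)  -  H[P(.|pi)]

so at fixed cross-entropy a higher-entropy policy (more options kept
open) carries strictly lower risk; the entropy term acts as an
exploration bonus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "GaussianBelief",
    "RiskDecomposition",
    "surprise",
    "entropy",
    "kl_discrete",
    "decompose_risk",
    "kl_gaussian",
]

#: tolerance on sum(probs) == 1 at construction
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteDistribution:
    """A labelled probability table over a finite state space.

    Carries both roles of the decision analysis: the preference prior
    P(S) and a policy-conditioned attainable-state distribution P(S|pi).

    Parameters
    ----------
    labels
        Unique, ordered state identifiers.
    probs
        Probabilities aligned with *labels*; non-negative, summing to 1
        within ``1e-9``.  Pass ``renormalize=True`` to rescale an
        unnormalized non-negative weight vector instead of raising.
    """

    labels: tuple
    probs: tuple = field(compare=True)

    def __init__(self, labels: Sequence, probs: Sequence[float], *,
                 renormalize: bool = False):
        labels = tuple(labels)
        p = np.asarray(probs, dtype=float)
        if len(labels) != p.size:
            raise ValueError(
                f"labels ({len(labels)}) and probs ({p.size}) differ in length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if p.size == 0:
            raise ValueError("distribution must have at least one state")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and >= 0")
        total = float(p.sum())
        if renormalize:
            if total <= 0:
                raise ValueError("cannot renormalize an all-zero weight vector")
            p = p / total
        elif abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"probabilities sum to {total!r}, not 1 (tolerance {NORMALIZATION_TOL})")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    def __len__(self) -> int:
        return len(self.labels)

    def prob(self, state) -> float:
        """Probability of a single state; raises KeyError for unknown labels."""
        try:
            return self.probs[self.labels.index(state)]
        except ValueError:
            raise KeyError(f"unknown state label: {state!r}") from None

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.probs))

    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass(frozen=True)
class GaussianBelief:
    """A univariate Gaussian belief over a continuous state coordinate."""

    mean: float
    sd: float

    def __post_init__(self):
        if not (self.sd > 0) or not math.isfinite(self.sd):
            raise ValueError(f"sd must be strictly positive, got {self.sd!r}")
        if not math.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean!r}")


class RiskDecomposition(NamedTuple):
    """Risk split into its expected-utility and entropy components.

    ``expected_utility_term`` is ``sum_s P(s|pi) log2 P(s)`` (<= 0; its
    negative is the cross-entropy), ``entropy_term`` is the entropy of
    the attainable-state distribution, and
    ``risk = -expected_utility_term - entropy_term``.
    """

    expected_utility_term: float
    entropy_term: float
    risk: float


def surprise(dist: DiscreteDistribution, state) -> float:
    """Surprisal -log2 P(state) in bits; ``inf`` for a zero-probability state.

    Minimal (0 bits) at a certain state, growing as the realized state
    becomes less preferred under the distribution.
    """
    p = dist.prob(state)  # KeyError for unknown labels
    if p == 0.0:
        return math.inf
    # np.log2, not math.log2: keeps surprise(dist, s) bit-identical to
    # the risk of a point-mass posterior on s computed by decompose_risk
    return float(-np.log2(p))


def entropy(dist: DiscreteDistribution) -> float:
    """Shannon entropy in bits, with the 0*log(0) := 0 convention."""
    p = dist.array()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _check_same_labels(posterior: DiscreteDistribution,
                       prior: DiscreteDistribution) -> None:
    if posterior.labels != prior.labels:
        raise ValueError(
            "distributions are over different state spaces: "
            f"{posterior.labels!r} vs {prior.labels!r}")


def kl_discrete(posterior: DiscreteDistribution,
                prior: DiscreteDistribution) -> float:
    """D_KL(posterior || prior) in bits.

    Returns ``inf`` (a sentinel, not an exception) when the posterior
    puts mass on a state the prior rules out — an infinitely risky
    policy still participates in rankings, last.
    """
    _check_same_labels(posterior, prior)
    q = posterior.array()
    p = prior.array()
    mask = q > 0
    if np.any(p[mask] == 0):
        return math.inf
    return float((q[mask] * np.log2(q[mask] / p[mask])).sum())


def decompose_risk(posterior: DiscreteDistribution,
                   prior: DiscreteDistribution) -> RiskDecomposition:
    """Split the policy risk into expected-utility and entropy terms.

    The identity ``risk == -EU - H`` holds exactly in exact arithmetic
    and to ~1e-12 in floats; ``risk`` here recomputes the sum term by
    term rather than calling :func:`kl_discrete`, so the two routes can
    be cross-checked.
    """
    _check_same_labels(posterior, prior)
    q = posterior.array()
    p = prior.array()
    mask = q > 0
    ent = entropy(posterior)
    if np.any(p[mask] == 0):
        return RiskDecomposition(-math.inf, ent, math.inf)
    eu = float((q[mask] * np.log2(p[mask])).sum())
    return RiskDecomposition(eu, ent, -eu - ent)


def kl_gaussian(posterior: GaussianBelief, prior: GaussianBelief) -> float:
    """D_KL between two univariate Gaussians, in bits.

    Closed form (nats, then divided by ln 2):

        ln(sd_prior/sd_post) + (sd_post^2 + (mu_post - mu_prior)^2)
                               / (2 sd_prior^2) - 1/2

    For equal sds this reduces to ``(d_mu)^2 / (2 sd^2 ln 2)`` bits:
    risk grows quadratically with the distance between the attainable
    mean and the goal mean.
    """
    nats = (math.log(prior.sd / posterior.sd)
            + (posterior.sd ** 2 + (posterior.mean - prior.mean) ** 2)
            / (2.0 * prior.sd ** 2)
            - 0.5)
    return nats / math.log(2.0)
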