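"""Independent brute-force oracle used to cross-check the package.

Everything here is computed by direct enumeration and plain ``math``
summation over Python dicts — no calls into klcontrol's information or
decision code — so agreement between the two routes is meaningful.
"""

import math


def oracle_kl(posterior: dict, prior: dict) -> float:
    """Direct-summation KL divergence in bits over labelled dicts."""
    assert set(posterior) == set(prior)
    total = 0.0
    for s, q in posterior.items():
        if q > 0:
            if prior[s] == 0:
                return math.inf
            total += q * math.log2(q / prior[s])
    return total


def oracle_entropy(dist: dict) -> float:
    return -sum(p * math.log2(p) for p in dist.values() if p > 0)


def oracle_posterior(game, policy) -> dict:
    """Enumerate the attainable-state distribution from the policy spec."""
    states = game.space.states
    if policy.kind == "forced_action":
        om = dict(zip(game.opponent_model.labels, game.opponent_model.probs))
        return {(e, a): (om[a] if e == policy.forced_ego_action else 0.0)
                for (e, a) in states}
    permitted = [(e, a) for (e, a) in states
                 if e not in policy.banned_ego_actions
                 and a not in policy.banned_alter_actions]
    return {s: (1.0 / len(permitted) if s in permitted else 0.0)
            for s in states}


def oracle_evaluate_game(game) -> dict:
    """Per-policy risk in bits by full enumeration; name -> risk."""
    prior = dict(zip(game.prior.labels, game.prior.probs))
    return {p.name: oracle_kl(oracle_posterior(game, p), prior)
            for p in game.policies}


def oracle_selection(risks: dict, tol: float = 1e-9):
    """(selected_or_None, tie_flag, tie_members) from a risk table."""
    finite = {k: v for k, v in risks.items() if math.isfinite(v)}
    if not finite:
        return None, len(risks) >= 2, sorted(risks)
    best = min(finite.values())
    members = [k for k, v in finite.items() if v - best <= tol]
    if len(members) >= 2:
        return None, True, members
    return members[0], False, members
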