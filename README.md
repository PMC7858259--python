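# klcontrol

Surprise-minimization (KL-control) decision analysis for two-agent
games: policy risk in bits, its expected-utility/entropy decomposition,
enforceable-contract policies, and the hawk/dove cooperation cut-off.

## The problem

In the free-energy view of behaviour, an agent's goals are a prior
probability distribution *P(S)* over states of the world, and reaching
a state *s* carries a surprise of −log₂ *P(s)* bits.  A policy π does
not lead to one state but to a distribution *P(S|π)* over attainable
states, and its **risk** — its expected future surprise — is the
Kullback-Leibler divergence

&nbsp;&nbsp;&nbsp;&nbsp;D<sub>KL</sub>[P(S|π) ‖ P(S)] = Σ<sub>s</sub> P(s|π) log₂ ( P(s|π) / P(s) )

which decomposes as *cross-entropy − entropy*: a low-risk policy both
aims at high-utility outcomes (low cross-entropy with the preferences)
and keeps many options open (high entropy over attainable states, an
exploration bonus).  The agent selects the policy with minimal risk;
when two policies tie at the minimum there is *no clear best policy* —
the decision-level stress condition.

`klcontrol` implements this analysis for two-agent (Ego–Alter) games:

- exact information primitives (surprisal, entropy, discrete and
  Gaussian KL, the risk decomposition), all in bits;
- a game model with reward-derived preference priors, forced-action
  policies, and enforceable contracts that ban hostile actions for
  *both* agents;
- a decision engine that evaluates a policy repertoire, selects the
  minimal-risk policy and flags ties as stress;
- a preference sweep that varies the exploitation reward, traces each
  policy's risk curve and bisects for the cooperation cut-off that
  separates dove-like (cooperating) from hawk-like (defecting) agents;
- generators for every input: the 9-state prisoner's-dilemma-structured
  game, Gaussian goal/attainable scenarios, restriction-effect
  fixtures, and seeded random games.

It is aimed at computational cognitive scientists and behavioural game
theorists who want a small, exactly-tested reference implementation of
KL-control policy selection in social games.

## Worked example

```python
from klcontrol import evaluate_all, find_cutoff, make_pd_fixture

game = make_pd_fixture(floor=0.0).game   # 9 states, 4 policies, T=5 R=3 P=1 S=0
for ev in evaluate_all(game).evaluations:
    print(f"{ev.policy_name:10s} {ev.risk_bits:.4f} bits")
est = find_cutoff(game, "Cooperate", "Policy 3", (5, 15), floor=0.0)
print(f"cut-off T* = {est.parameter_value:.4f}, "
      f"exploit probability {est.exploit_probability:.4f}")
```

prints

```
Policy 1   inf bits
Policy 2   inf bits
Policy 3   1.3906 bits
Cooperate  0.9386 bits
cut-off T* = 8.0000, exploit probability 0.2759
```

The contract ("Cooperate", banning the hostile action E3/A3 for both
agents) concentrates the attainable states on the four mutually
friendly outcomes and keeps 2 bits of options open, so its risk
log₂(23/12) ≈ 0.9386 bits undercuts the hostile Policy 3
(1.3906 bits); forcing a friendly action alone risks being exploited in
a state the preferences rule out, hence infinite risk (finite once a
tiny reward floor is applied — the default fixture uses 10⁻⁶).
Cooperation therefore emerges from surprise minimization.  Raising the
temptation reward T moves the prior toward the exploitation states;
the curves cross at T* = 8 (per-state exploitation probability
8/29 ≈ 0.2759): below it the agent is a dove and cooperates, above it
a hawk, and exactly at it both policies tie — no clear best policy,
and the stress flag raises.

The `examples/` directory holds one short narrative script per
capability; a thin CLI mirrors them
(`klcontrol evaluate --fixture pd`, `klcontrol sweep --fixture pd
--grid 2:12:1 --bracket 5:15`, `klcontrol cutoff`, `klcontrol
generate --seed 42`, `klcontrol fixture`).  Game specifications are
JSON documents (schema in `src/klcontrol/schemas/`); reports are
written as TSV and JSON with 12 significant digits.

## Layout

- `src/klcontrol/` — `information` (primitives), `game` (model and
  config I/O), `decision` (evaluation/selection), `sweep` (cut-off
  analysis), `synthetic` (generators), `reporting` + `cli`.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions, limitations.
- `tests/` — unit, property and acceptance suites with an independent
  brute-force oracle.
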