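"""Cooperation minimizes risk in the 9-state Ego-Alter game.

Ego and Alter each have two friendly actions and one hostile one; Ego's
rewards have prisoner's-dilemma structure (exploiting beats mutual
friendliness beats mutual hostility beats being exploited).  Forcing
any single action is risky; the enforceable contract that bans the
hostile action for both agents concentrates the attainable states on
outcomes Ego actually values and keeps four options open, so it has
the smallest expected future surprise.
"""

from klcontrol import detect_stress, evaluate_all, make_pd_fixture

bundle = make_pd_fixture()
game = bundle.game
print(bundle.description)
print("\nprior preferences (from rewards T=5, R=3, P=1, S=0):")
for s, p in zip(game.prior.labels, game.prior.probs):
    print(f"  {s}: {p:.4f}")

report = evaluate_all(game)
print("\npolicy risks (bits):")
for ev in report.evaluations:
    print(f"  {ev.policy_name:10s} risk={ev.risk_bits:8.4f}  "
          f"cross-entropy={-ev.expected_utility_term:8.4f}  "
          f"entropy bonus={ev.entropy_term:6.4f}")
stressed, explanation = detect_stress(report)
print("\nselected:", report.selected, "| stress:", stressed)
print(explanation)
print("\nCooperate's 0.94 bits beat the hostile Policy 3's 1.39 bits: "
      "minimizing expected surprise makes Ego sign the contract.")
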