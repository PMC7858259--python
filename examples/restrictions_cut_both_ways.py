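"""A restriction can lower or raise the minimal risk, depending on context.

Banning states always costs entropy (fewer options kept open), so a
contract pays off only when the expected-utility gain from excluding
bad outcomes outweighs that loss.  Two constructed games show both
directions.
"""

from klcontrol import evaluate_all, make_restriction_pair

for bundle in make_restriction_pair():
    report = evaluate_all(bundle.game)
    contract = report.evaluation("Contract").risk_bits
    best_forced = min(ev.risk_bits for ev in report.evaluations
                      if ev.policy_name != "Contract")
    print(bundle.description)
    print(f"  contract risk {contract:.4f} bits vs best unrestricted "
          f"{best_forced:.4f} bits -> "
          f"{'restriction helps' if contract < best_forced else 'restriction hurts'}\n")

print("A rule that forecloses likely, strongly aversive outcomes is worth "
      "its entropy cost; one that forecloses a desirable outcome is not.")
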