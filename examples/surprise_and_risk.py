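"""Surprisal, entropy and policy risk on small hand-built distributions.

An agent's goals are a probability distribution over states; reaching a
state carries a surprise of -log2 of its probability.  A policy's risk
is the KL divergence between the states it makes attainable and those
goals, and splits into a cross-entropy (negative expected-utility) term
minus an entropy bonus for keeping options open.
"""

from klcontrol import (DiscreteDistribution, GaussianBelief, decompose_risk,
                       entropy, kl_gaussian, make_gaussian_fixture, surprise)

goals = DiscreteDistribution(["good", "okay", "bad", "awful"],
                             [0.4, 0.3, 0.2, 0.1])
print("surprise at 'good':  ", round(surprise(goals, "good"), 4), "bits")
print("surprise at 'awful': ", round(surprise(goals, "awful"), 4), "bits")

attainable = DiscreteDistribution(goals.labels, [0.25] * 4)
eu, ent, risk = decompose_risk(attainable, goals)
print("\npolicy spreading mass evenly over all four states:")
print("  cross-entropy", round(-eu, 4), "- entropy", round(ent, 4),
      "= risk", round(risk, 4), "bits")
print(f"  (the {entropy(attainable):.0f}-bit entropy bonus for keeping all "
      "four options open offsets most of the cross-entropy)")

# continuous version: goal mean 3.0, attainable mean 5.3, unit spreads
goal, att = make_gaussian_fixture()
print("\nGaussian scenario: risk =", round(kl_gaussian(att, goal), 4), "bits")
near = GaussianBelief(4.15, 1.0)  # half the distance
print("half the distance:  risk =", round(kl_gaussian(near, goal), 4),
      "bits (quadratic: a quarter of the above)")
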