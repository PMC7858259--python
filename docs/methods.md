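# Methods

## Model

An agent's preferences over a finite set of joint states are a prior
probability distribution P(S); a policy π induces a distribution
P(S|π) over the states it makes attainable.  The risk of π is

    D_KL[P(S|π) || P(S)] = Σ_s P(s|π) log2( P(s|π) / P(s) )   [bits]

the policy's expected future surprise.  All reported quantities use
base-2 logarithms; natural-log intermediates are converted.

The divergence decomposes identically as

    risk = cross-entropy − entropy
         = −Σ_s P(s|π) log2 P(s)  −  H[P(S|π)]

The first term is the negative expected-utility alignment with the
preferences; the second is an entropy bonus: at fixed cross-entropy, a
policy that keeps more attainable states open is strictly less risky.
The decomposition is sometimes written with the entropy term added
rather than subtracted; only the subtracted form is algebraically
consistent with the divergence above, and it is also the form that
matches the exploration-bonus interpretation (more options → less
risk), so that is what the package implements.  `decompose_risk`
computes the two terms independently of `kl_discrete`, and the test
suite checks the identity to 1e-12 on random distribution pairs.

For continuous one-dimensional states the package provides the
Gaussian closed form; with equal spreads it reduces to
(Δμ)²/(2σ² ln 2) bits — risk quadratic in the distance between the
attainable mean and the goal mean — and is cross-checked against
numerical quadrature of the KL integrand to 1e-6 bits.

## Two-agent games

A game couples Ego and Alter; the joint state is (ego_action,
alter_action), ego-major.  Conventions the model fixes:

- **Preference encoding.**  prior(s) ∝ max(reward(s), floor·max_reward),
  linearly normalized.  Linear (rather than softmax) normalization makes
  the prior scale-invariant in the rewards and strictly monotone in each
  single reward, so "raise the reward for exploitation, keep all else
  fixed" maps cleanly onto the probability axis.  With the canonical
  prisoner's-dilemma payoffs T=5, R=3, P=1, S=0 it puts 5/23 ≈ 0.2174
  on each exploitation state — a low-to-medium exploitation preference.
- **Reward floor** (default 1e-6, unitless fraction of the maximum
  reward).  Zero-reward ("sucker") states otherwise get prior 0 and any
  policy that can reach them infinite risk; the floor keeps those risks
  large but finite and readable (≈7.75 bits on the shipped fixture).
  `floor=0` gives the exact analysis; infinite risks are returned as an
  `inf` sentinel, never raised, so rankings still work (infinite-risk
  policies rank last and are never selected unless all are infinite).
- **Forced-action posterior.**  Ego knows nothing about Alter by
  default, so the forced row is spread per a uniform opponent model
  (overridable in the game config).
- **Contract posterior.**  Uniform over all permitted joint states —
  the maximum-entropy choice given that the contract only rules states
  out; nothing in the scenario fixes how Ego's own action is
  distributed under a contract.
- **Tie tolerance** 1e-9 bits.  Two policies within it share the
  minimum; the tie is reported as the no-clear-best-policy (stress)
  condition and never broken silently, because the tie itself is the
  construct of interest.

## Exploitation sweep and cut-off

Exploitation states are the hostile ego action crossed with the
friendly alter actions; by default they are inferred from the game's
contract policy (the action it bans for Ego is the hostile one).  The
default sweep is **reward-space**: set the exploitation reward to each
grid value and re-derive the prior.  A **probability-space** sweep
(set each exploitation state's prior probability, rescale the rest
proportionally) is provided for plotting against a probability axis;
its grid values are per-exploit-state probabilities.

On the shipped game (friendly reward R=3, mutual-hostility P=1), the
cooperative contract's risk is log2(N/12) and the hostile policy's is
log2(N/3) − (2/3)log2 T with N = 13 + 2T, so their difference
(2/3)log2 T − 2 is monotone with the single root T* = 8, i.e. a
per-state exploitation probability of 8/29 ≈ 0.2759.  The cut-off is
located by bisection (parameter tolerance 1e-10, residual risk
difference required < 1e-9 bits) rather than grid interpolation, so
its precision does not depend on grid density.  Note the individual
hostile-policy curve is decreasing only for T < 4R + P (= 13 here);
beyond that the hostile row's own over-concentration starts to raise
its risk again, but the *difference* of the two curves stays monotone,
so the crossing is unique regardless.

Classification compares the game's current per-state exploitation
probability with the cut-off: below → dove (cooperates), above → hawk
(defects), within 1e-9 → borderline, which coincides with the tie/
stress flag of the decision report.

## Synthetic data

The generators define the study conditions:

- `make_pd_fixture` — the 3×3 Ego–Alter game.  The 9-state structure,
  the four-policy repertoire (three forced actions plus the contract
  banning E3/A3) and the uniform opponent model are fixed by the
  scenario; the numeric rewards are a documented *reconstruction* using
  canonical prisoner's-dilemma payoffs 5/3/1/0, chosen because linear
  normalization then reproduces the stated ≈0.22 exploitation
  preference.  The reconstruction's cut-off probability (0.2759)
  accordingly differs from the ≈0.24 quoted for the original, whose
  exact prior was never published; only the qualitative structure
  (single crossing, dove below, hawk above, tie at the crossing) is
  recoverable, and that is what the tests assert.
- `make_gaussian_fixture` — goal mean 3.0, attainable mean 5.3, both
  sds 1.0 by default (the original spread being unstated, unit sd is
  the neutral choice; the risk at these defaults is 3.8159 bits).
- `generate_random_game` — rewards i.i.d. Gamma(c, 1/c) (mean 1): one
  parameter c controls preference peakedness (small = peaked, large =
  flat); policies are one forced per ego action plus a contract banning
  the lowest-total-reward ego and alter actions.  Pure function of the
  seed.
- `make_restriction_pair` — two constructed games verified at build
  time: one where a contract banning a likely, strongly aversive alter
  action beats every unrestricted policy, one where a contract banning
  the action behind the single most desirable state loses to the best
  forced policy.

What these generators do *not* emulate: empirical behavioural data,
asymmetric information, repeated play, belief updating about the
opponent, or populations of more than two agents.  Passing tests show
the decision mathematics is exact under the stated conditions, not
that real agents behave this way.

## Numerical choices

- Distribution construction tolerates |Σp − 1| ≤ 1e-9; renormalization
  only on request.
- `surprise` and `decompose_risk` share the same log implementation so
  the identity "surprisal of s = risk of a point-mass policy on s"
  holds bit-exactly.
- Reports (TSV/JSON) carry 12 significant digits; written values
  round-trip to the in-memory ones at that precision, and identical
  inputs produce byte-identical report files.
- Problem sizes: property suites use ~1000 random distributions and
  200 random games with 2–4 actions per side, which keeps the full
  test run under half a minute on one CPU while exercising every
  branch of the selection logic.

## Limitations

- The reward→prior map is a modelling choice; any strictly monotone
  normalization would preserve the qualitative results but move the
  numeric cut-off.
- The contract posterior's uniformity is an assumption, not a derived
  result; a non-uniform self-model under contracts would change the
  entropy bonus of cooperative policies.
- Continuous-state risk is implemented for Gaussians only.
- Stress is modelled purely as the decision-level tie; no physiology.
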