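"""Game model: preference encoding, posteriors, contracts, config I/O."""

import json
import math

import numpy as np
import pytest

from klcontrol import (DiscreteDistribution, GameConfigError, GameSpec,
                       JointStateSpace, PolicySpec, RewardMatrix,
                       apply_contract, build_policy_posterior,
                       encode_preferences, game_to_config, load_game,
                       make_pd_fixture, save_game)


@pytest.fixture
def space():
    return JointStateSpace(("E1", "E2", "E3"), ("A1", "A2", "A3"))


class TestJointStateSpace:
    def test_states_are_ego_major_cartesian_product(self, space):
        assert len(space) == 9
        assert space.states[:3] == (("E1", "A1"), ("E1", "A2"), ("E1", "A3"))
        assert space.states[-1] == ("E3", "A3")

    def test_duplicate_actions_rejected(self):
        with pytest.raises(ValueError):
            JointStateSpace(("E1", "E1"), ("A1",))


class TestEncodePreferences:
    def test_pd_rewards_normalize_to_stated_preferences(self, pd_game_exact):
        prior = pd_game_exact.prior.as_dict()
        assert prior[("E3", "A1")] == pytest.approx(5 / 23, abs=1e-12)
        assert prior[("E3", "A2")] == pytest.approx(5 / 23, abs=1e-12)
        assert prior[("E1", "A1")] == pytest.approx(3 / 23, abs=1e-12)
        assert prior[("E3", "A3")] == pytest.approx(1 / 23, abs=1e-12)
        assert prior[("E1", "A3")] == 0.0
        # the exploitation preference the scenario quotes as ~0.22
        assert round(prior[("E3", "A1")], 2) == 0.22

    def test_equal_rewards_give_uniform_prior(self):
        rm = RewardMatrix({("E1", "A1"): 2.0, ("E1", "A2"): 2.0,
                           ("E2", "A1"): 2.0, ("E2", "A2"): 2.0})
        prior = encode_preferences(rm)
        assert all(p == pytest.approx(0.25) for p in prior.probs)

    def test_floor_keeps_zero_reward_states_positive(self):
        rm = RewardMatrix({("E1", "A1"): 1.0, ("E1", "A2"): 0.0})
        prior = encode_preferences(rm, floor=0.001)
        assert prior.probs == pytest.approx((1 / 1.001, 0.001 / 1.001))

    def test_all_zero_rewards_rejected(self):
        with pytest.raises(ValueError):
            RewardMatrix({("E1", "A1"): 0.0})

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        states = [("E1", "A1"), ("E1", "A2"), ("E2", "A1"), ("E2", "A2")]
        for _ in range(20):
            vals = rng.random(4)
            a = encode_preferences(RewardMatrix(dict(zip(states, vals))), 1e-4)
            b = encode_preferences(
                RewardMatrix(dict(zip(states, vals * 37.5))), 1e-4)
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_raising_one_reward_raises_only_its_probability(self):
        states = [("E1", "A1"), ("E1", "A2"), ("E2", "A1"), ("E2", "A2")]
        base = dict(zip(states, [1.0, 2.0, 3.0, 4.0]))
        lo = encode_preferences(RewardMatrix(base), 0.0).as_dict()
        base[("E1", "A2")] = 2.5
        hi = encode_preferences(RewardMatrix(base), 0.0).as_dict()
        assert hi[("E1", "A2")] > lo[("E1", "A2")]
        for s in states:
            if s != ("E1", "A2"):
                assert hi[s] < lo[s]


class TestApplyContract:
    def test_banning_hostile_actions_leaves_friendly_block(self, space):
        permitted = apply_contract(space, {"E3"}, {"A3"})
        assert permitted == (("E1", "A1"), ("E1", "A2"),
                             ("E2", "A1"), ("E2", "A2"))

    def test_empty_ban_is_identity(self, space):
        assert apply_contract(space, set(), set()) == space.states

    def test_banning_everything_is_an_error(self, space):
        with pytest.raises(ValueError):
            apply_contract(space, {"E1", "E2", "E3"}, set())

    def test_matches_brute_force_filter_on_random_spaces(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            ne, na = rng.integers(2, 5, size=2)
            sp = JointStateSpace([f"E{i}" for i in range(ne)],
                                 [f"A{j}" for j in range(na)])
            be = set(rng.choice(sp.ego_actions,
                                size=rng.integers(0, ne), replace=False))
            ba = set(rng.choice(sp.alter_actions,
                                size=rng.integers(0, na), replace=False))
            expected = tuple((e, a) for (e, a) in sp.states
                             if e not in be and a not in ba)
            if expected:
                assert apply_contract(sp, be, ba) == expected


class TestPolicyPosterior:
    def test_forced_action_spreads_mass_per_opponent_model(self, pd_game):
        post = build_policy_posterior(pd_game, pd_game.policy("Policy 1"))
        assert post.as_dict() == pytest.approx(
            {s: (1 / 3 if s[0] == "E1" else 0.0) for s in pd_game.space.states})

    def test_contract_is_uniform_over_permitted_states(self, pd_game):
        post = build_policy_posterior(pd_game, pd_game.policy("Cooperate"))
        friendly = {(e, a) for e in ("E1", "E2") for a in ("A1", "A2")}
        assert post.as_dict() == pytest.approx(
            {s: (0.25 if s in friendly else 0.0) for s in pd_game.space.states})

    def test_hostile_forced_policy_row(self, pd_game):
        post = build_policy_posterior(pd_game, pd_game.policy("Policy 3"))
        assert post.as_dict() == pytest.approx(
            {s: (1 / 3 if s[0] == "E3" else 0.0) for s in pd_game.space.states})

    def test_nonuniform_opponent_model_is_respected(self, pd_game):
        from dataclasses import replace
        skewed = replace(pd_game, opponent_model=DiscreteDistribution(
            ("A1", "A2", "A3"), (0.6, 0.3, 0.1)))
        post = build_policy_posterior(skewed, skewed.policy("Policy 2"))
        assert post.prob(("E2", "A1")) == pytest.approx(0.6)
        assert post.prob(("E2", "A3")) == pytest.approx(0.1)

    def test_every_posterior_is_valid_over_the_space(self, pd_game):
        for policy in pd_game.policies:
            post = build_policy_posterior(pd_game, policy)
            assert post.labels == pd_game.space.states
            assert sum(post.probs) == pytest.approx(1.0, abs=1e-12)
            assert min(post.probs) >= 0.0


class TestConfigIO:
    def test_bundled_fixture_config_loads_to_nine_state_game(self):
        from importlib.resources import files
        path = files("klcontrol") / "fixtures" / "prisoners_dilemma.json"
        game = load_game(str(path))
        assert len(game.space) == 9
        assert [p.name for p in game.policies] == [
            "Policy 1", "Policy 2", "Policy 3", "Cooperate"]
        fixture_game = make_pd_fixture().game
        np.testing.assert_allclose(game.prior.probs, fixture_game.prior.probs,
                                   atol=1e-12)

    def test_round_trip_is_exact(self, tmp_path, pd_game):
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        save_game(pd_game, p1)
        loaded = load_game(p1)
        assert loaded == pd_game
        save_game(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_explicit_prior_overrides_rewards(self, pd_game):
        doc = game_to_config(pd_game, explicit_prior=True)
        doc["prior"] = {k: 1 / 9 for k in doc["rewards"]}
        game = load_game(doc)
        assert all(p == pytest.approx(1 / 9) for p in game.prior.probs)

    def test_unknown_action_in_policy_names_the_label(self, pd_game):
        doc = game_to_config(pd_game)
        doc["policies"][0]["forced_ego_action"] = "E9"
        with pytest.raises(GameConfigError, match="E9"):
            load_game(doc)

    def test_schema_violation_reports_field_path(self, pd_game):
        doc = game_to_config(pd_game)
        doc["policies"][0].pop("name")
        with pytest.raises(GameConfigError, match="policies"):
            load_game(doc)

    def test_missing_file_is_a_config_error(self):
        with pytest.raises(GameConfigError):
            load_game("no/such/config.json")

    def test_missing_reward_entry_detected(self, pd_game):
        doc = game_to_config(pd_game, explicit_prior=False)
        doc["rewards"].pop("E1,A1")
        with pytest.raises(GameConfigError, match="missing"):
            load_game(doc)

    def test_shipped_schema_is_valid_json(self):
        from importlib.resources import files
        schema = json.loads(
            (files("klcontrol") / "schemas" / "game_config.schema.json")
            .read_text())
        assert schema["type"] == "object"
        assert "rewards" in schema["properties"]


class TestGameSpecInvariants:
    def test_prior_label_mismatch_rejected(self, pd_game):
        bad = DiscreteDistribution(["x", "y"], [0.5, 0.5])
        with pytest.raises(ValueError):
            GameSpec(space=pd_game.space, rewards=pd_game.rewards, prior=bad,
                     policies=pd_game.policies,
                     opponent_model=pd_game.opponent_model)

    def test_contract_banning_all_states_rejected(self, pd_game):
        bad = PolicySpec("Bad", "contract",
                         banned_ego_actions=frozenset({"E1", "E2", "E3"}))
        with pytest.raises(ValueError):
            GameSpec(space=pd_game.space, rewards=pd_game.rewards,
                     prior=pd_game.prior, policies=(bad,),
                     opponent_model=pd_game.opponent_model)
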