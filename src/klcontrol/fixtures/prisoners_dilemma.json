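{
  "agent_id": "Ego",
  "agents": {
    "alter": [
      "A1",
      "A2",
      "A3"
    ],
    "ego": [
      "E1",
      "E2",
      "E3"
    ]
  },
  "floor": 1e-06,
  "opponent_model": {
    "A1": 0.3333333333333333,
    "A2": 0.3333333333333333,
    "A3": 0.3333333333333333
  },
  "policies": [
    {
      "forced_ego_action": "E1",
      "kind": "forced_action",
      "name": "Policy 1"
    },
    {
      "forced_ego_action": "E2",
      "kind": "forced_action",
      "name": "Policy 2"
    },
    {
      "forced_ego_action": "E3",
      "kind": "forced_action",
      "name": "Policy 3"
    },
    {
      "banned_alter_actions": [
        "A3"
      ],
      "banned_ego_actions": [
        "E3"
      ],
      "kind": "contract",
      "name": "Cooperate"
    }
  ],
  "rewards": {
    "E1,A1": 3.0,
    "E1,A2": 3.0,
    "E1,A3": 0.0,
    "E2,A1": 3.0,
    "E2,A2": 3.0,
    "E2,A3": 0.0,
    "E3,A1": 5.0,
    "E3,A2": 5.0,
    "E3,A3": 1.0
  }
}
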