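{
  "$defs": {
    "_PolicyConfig": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "kind": {
          "enum": [
            "forced_action",
            "contract"
          ],
          "title": "Kind",
          "type": "string"
        },
        "forced_ego_action": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Forced Ego Action"
        },
        "banned_ego_actions": {
          "default": [],
          "items": {
            "type": "string"
          },
          "title": "Banned Ego Actions",
          "type": "array"
        },
        "banned_alter_actions": {
          "default": [],
          "items": {
            "type": "string"
          },
          "title": "Banned Alter Actions",
          "type": "array"
        }
      },
      "required": [
        "name",
        "kind"
      ],
      "title": "_PolicyConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "agents": {
      "additionalProperties": {
        "items": {
          "type": "string"
        },
        "type": "array"
      },
      "propertyNames": {
        "enum": [
          "ego",
          "alter"
        ]
      },
      "title": "Agents",
      "type": "object"
    },
    "rewards": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Rewards",
      "type": "object"
    },
    "policies": {
      "items": {
        "$ref": "#/$defs/_PolicyConfig"
      },
      "title": "Policies",
      "type": "array"
    },
    "prior": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Prior"
    },
    "opponent_model": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Opponent Model"
    },
    "floor": {
      "default": 1e-06,
      "title": "Floor",
      "type": "number"
    },
    "agent_id": {
      "default": "Ego",
      "title": "Agent Id",
      "type": "string"
    }
  },
  "required": [
    "agents",
    "rewards",
    "policies"
  ],
  "title": "klcontrol game config",
  "type": "object",
  "description": "Two-agent game specification: action sets, a reward matrix keyed by 'ego_action,alter_action', a policy repertoire, and optional explicit prior / opponent model / reward floor."
}
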