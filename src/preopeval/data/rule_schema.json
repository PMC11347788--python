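{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Preoperative-evaluation rule pack",
  "description": "Normative description of the rule-set file format. The package loader enforces this schema (including rejection of unknown keys) with its own strict validator.",
  "type": "object",
  "additionalProperties": false,
  "required": ["version", "rules"],
  "properties": {
    "version": {"type": "string"},
    "observations": {
      "description": "Path to an observation dictionary file, or an inline list of observation definitions.",
      "oneOf": [{"type": "string"}, {"type": "array"}]
    },
    "scores": {"type": "array", "items": {"type": "string"}},
    "rules": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/rule"}}
  },
  "$defs": {
    "rule": {
      "type": "object",
      "additionalProperties": false,
      "required": ["rule_id", "action", "conditions"],
      "properties": {
        "rule_id": {"type": "string"},
        "action": {
          "type": "string",
          "pattern": "^(ECG|echocardiography|cardiac_stress_test|chest_xray|pulmonary_function|carotid_doppler|laboratory:.+|other:.+)$"
        },
        "source": {"enum": ["ESAIC", "ESC", "DGAI", "consensus"]},
        "conditions": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/condition"}}
      }
    },
    "condition": {
      "type": "object",
      "properties": {
        "grade": {"enum": ["1A", "1B", "1C", "2A", "2B", "2C", "none"]},
        "tree": {"$ref": "#/$defs/tree"},
        "atom": {"$ref": "#/$defs/predicate"},
        "all_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}},
        "any_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}},
        "not": {"$ref": "#/$defs/expr"}
      },
      "additionalProperties": false
    },
    "expr": {
      "type": "object",
      "minProperties": 1,
      "maxProperties": 1,
      "properties": {
        "atom": {"$ref": "#/$defs/predicate"},
        "all_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}},
        "any_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expr"}},
        "not": {"$ref": "#/$defs/expr"}
      },
      "additionalProperties": false
    },
    "tree": {
      "oneOf": [
        {"enum": ["fire", "no_fire"]},
        {
          "type": "object",
          "additionalProperties": false,
          "required": ["if", "then", "else"],
          "properties": {
            "if": {"$ref": "#/$defs/predicate"},
            "then": {"$ref": "#/$defs/tree"},
            "else": {"$ref": "#/$defs/tree"}
          }
        }
      ]
    },
    "predicate": {
      "type": "object",
      "additionalProperties": false,
      "required": ["target", "op"],
      "properties": {
        "target": {"type": "string"},
        "op": {"enum": ["is_yes", "is_no", "equals", "lt", "le", "gt", "ge", "in_set"]},
        "value": {}
      }
    }
  }
}
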