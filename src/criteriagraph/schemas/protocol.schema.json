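{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/criteriagraph/protocol.schema.json",
  "title": "Trial protocol document",
  "description": "Structured decomposition of a clinical trial's eligibility criteria into a DAG of independent (extracted) and dependent (computed) variables. The package reader enforces these constraints in code and reports violations as JSON-pointer paths.",
  "type": "object",
  "additionalProperties": false,
  "required": ["id", "name", "criteria", "variables"],
  "properties": {
    "id": {"type": "string"},
    "name": {"type": "string"},
    "criteria": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "text", "kind", "roots"],
        "properties": {
          "id": {"type": "string"},
          "text": {"type": "string"},
          "kind": {"enum": ["inclusion", "exclusion"]},
          "roots": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "combinator": {"enum": ["all", "any", null]}
        }
      }
    },
    "variables": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "name", "dependency", "data_type"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "dependency": {"enum": ["independent", "dependent"]},
          "data_type": {
            "enum": ["integer", "float", "boolean", "timestamp", "text", "indeterminate"]
          },
          "scope": {"enum": ["many_per_note", "one_per_note", "one_per_patient"]},
          "aggregation": {
            "enum": ["most_frequent", "first_value", "last_value",
                     "earliest_occurrence", "latest_occurrence", "most_recent"]
          },
          "instructions": {"type": "string"},
          "inputs": {"type": "array", "items": {"type": "string"}},
          "logic": {"$ref": "#/$defs/logicNode"}
        }
      }
    }
  },
  "$defs": {
    "logicNode": {
      "oneOf": [
        {"type": "null"},
        {
          "type": "object",
          "additionalProperties": false,
          "required": ["op"],
          "properties": {
            "op": {
              "enum": ["and", "or", "not", "eq", "ne", "lt", "le", "gt", "ge",
                       "add", "sub", "count", "temporal_gap", "lit", "var"]
            },
            "args": {"type": "array", "items": {"$ref": "#/$defs/logicNode"}},
            "value": {},
            "value_type": {
              "enum": ["integer", "float", "boolean", "timestamp", "text", "indeterminate"]
            },
            "id": {"type": "string"},
            "unit": {"enum": ["days", "months"]}
          }
        }
      ]
    }
  }
}
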