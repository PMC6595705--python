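{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "EvaluationSummary",
  "description": "Cross-validated prediction-error summary written by the evaluate pipeline stage.",
  "type": "object",
  "required": ["endpoint", "n_complete_cases", "ibs", "p_values", "curves", "metadata"],
  "properties": {
    "endpoint": {"type": "string", "enum": ["os", "pfs"]},
    "n_complete_cases": {"type": "integer", "minimum": 0},
    "ibs": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0.0, "maximum": 1.0}
    },
    "p_values": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0.0, "maximum": 1.0}
    },
    "curves": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["times", "brier"],
        "properties": {
          "times": {"type": "array", "items": {"type": "number"}},
          "brier": {"type": "array", "items": {"type": "number"}}
        }
      }
    },
    "metadata": {
      "type": "object",
      "required": ["subsample_size", "n_replicates", "seed", "horizon"],
      "properties": {
        "subsample_size": {"type": "integer"},
        "n_replicates": {"type": "integer"},
        "n_used": {"type": "integer"},
        "seed": {"type": "integer"},
        "horizon": {"type": "number"},
        "comparison_test": {"type": "string"}
      }
    },
    "n_dropped_replicates": {"type": "integer"}
  }
}
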