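{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "MPS I severity prediction report",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["patient_id", "verdict", "decisive_step", "trace"],
    "properties": {
      "patient_id": {"type": "string", "minLength": 1},
      "verdict": {"enum": ["H", "non-H", "indeterminate"]},
      "decisive_step": {"enum": ["genotype", "activity", "clinical", "none"]},
      "trace": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["step", "verdict", "rationale"],
          "properties": {
            "step": {"enum": ["genotype", "activity", "clinical"]},
            "verdict": {"enum": ["H", "non-H", "pass-through"]},
            "rationale": {"type": "string"}
          },
          "additionalProperties": false
        }
      }
    },
    "additionalProperties": false
  }
}
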