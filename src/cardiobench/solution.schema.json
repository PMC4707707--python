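{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "cardiobench solution archive metadata",
  "type": "object",
  "required": ["problem", "order", "n_dofs", "max_incompressibility_error", "log"],
  "properties": {
    "problem": {"type": ["integer", "null"], "minimum": 1, "maximum": 3},
    "resolution": {"type": ["array", "null"], "items": {"type": "integer", "minimum": 1}},
    "order": {"type": "integer", "enum": [1, 2]},
    "n_dofs": {"type": "integer", "minimum": 1},
    "max_incompressibility_error": {"type": "number", "minimum": 0},
    "multiplier": {"type": "array", "items": {"type": "number"}},
    "log": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["lambda", "iterations", "residuals", "max_J_err"],
        "properties": {
          "lambda": {"type": "number", "minimum": 0, "maximum": 1},
          "iterations": {"type": "integer", "minimum": 0},
          "residuals": {"type": "array", "items": {"type": "number"}},
          "max_J_err": {"type": "number", "minimum": 0},
          "wall_s": {"type": "number", "minimum": 0}
        }
      }
    }
  }
}
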