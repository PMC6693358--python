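{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Simulation definition",
  "description": "Experiment description with five sections: inputs (stimuli and their target cell-group selectors), responses (recorded variables), setup (wiring overrides, EES recruitment model), runs (duration/dt/seed/overrides), plots (analysis specs).",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "inputs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["stimulus", "target"],
        "properties": {
          "stimulus": {
            "type": "object",
            "required": ["kind"],
            "properties": {
              "kind": {"enum": ["iclamp_piecewise", "periodic_ees"]},
              "breakpoints": {"type": "array", "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}},
              "rate": {"type": "number", "exclusiveMinimum": 0},
              "onset_delay": {"type": "number", "minimum": 0},
              "amplitude": {"type": "number"},
              "n_pulses": {"type": "integer", "minimum": 1},
              "end_time": {"type": "number", "exclusiveMinimum": 0}
            }
          },
          "target": {}
        }
      }
    },
    "responses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "target"],
        "properties": {
          "variable": {"enum": ["v", "spike", "i_na"]},
          "target": {}
        }
      }
    },
    "setup": {
      "type": "object",
      "properties": {
        "ees_recruitment": {
          "type": "object",
          "properties": {
            "t_aff": {"type": "number"},
            "sat_aff": {"type": "number"},
            "t_mn": {"type": "number"},
            "sat_mn": {"type": "number"}
          }
        }
      }
    },
    "runs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["duration"],
        "properties": {
          "duration": {"type": "number", "exclusiveMinimum": 0},
          "dt": {"type": "number", "exclusiveMinimum": 0},
          "seed": {"type": "integer"},
          "overrides": {"type": "object"}
        }
      }
    },
    "plots": {"type": "array", "items": {"type": "object"}}
  }
}
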