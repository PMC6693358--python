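{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Model definition",
  "description": "Simulator-agnostic structured model of a spinal sensorimotor circuit: five core sections plus auxiliary data (random cell positions, instantiated cell templates, references). Coordinates are micrometres, right-handed, z increasing rostrally.",
  "type": "object",
  "required": ["info", "regions", "segments", "cell_groups", "net_connections", "aux"],
  "additionalProperties": false,
  "properties": {
    "info": {"type": "object"},
    "segments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "length", "rostro_caudal_offset"],
        "properties": {
          "name": {"type": "string"},
          "length": {"type": "number", "exclusiveMinimum": 0},
          "rostro_caudal_offset": {"type": "number"},
          "central_canal_xy": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
        }
      }
    },
    "regions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "segment", "lamina", "side", "geometry"],
        "properties": {
          "name": {"type": "string"},
          "segment": {"type": "string"},
          "lamina": {"type": "string"},
          "side": {"enum": ["L", "R", ""]},
          "geometry": {
            "type": "object",
            "required": ["kind", "z"],
            "properties": {
              "kind": {"enum": ["box", "extruded_polygon"]},
              "x": {"type": "array", "items": {"type": "number"}},
              "y": {"type": "array", "items": {"type": "number"}},
              "z": {"type": "array", "items": {"type": "number"}},
              "vertices": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}}
            }
          }
        }
      }
    },
    "cell_groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "region", "template", "count", "neuron_type"],
        "properties": {
          "name": {"type": "string"},
          "region": {"type": "string"},
          "template": {"type": "string"},
          "count": {"$ref": "#/$defs/random_scalar"},
          "neuron_type": {"enum": ["AlphaMoto", "IaAfferent", "IIAfferent", "IaInterneuron", "ExcInterneuron"]},
          "target_muscle": {"type": "string"},
          "realized_count": {"type": "integer", "minimum": 0}
        }
      }
    },
    "net_connections": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "dest", "sign", "weight", "delay", "tau", "e_rev", "convergence"],
        "properties": {
          "source": {"type": "string"},
          "dest": {"type": "string"},
          "sign": {"enum": ["excitatory", "inhibitory"]},
          "weight": {"$ref": "#/$defs/random_scalar"},
          "delay": {"type": "number", "exclusiveMinimum": 0},
          "tau": {"type": "number", "exclusiveMinimum": 0},
          "e_rev": {"type": "number"},
          "convergence": {"$ref": "#/$defs/random_scalar"},
          "rule": {"type": "string"},
          "realized_weight": {"type": "number"},
          "realized_convergence": {"type": "integer", "minimum": 0}
        }
      }
    },
    "aux": {
      "type": "object",
      "properties": {
        "positions": {"type": "object"},
        "templates": {"type": "object"},
        "references": {"type": "object"}
      }
    }
  },
  "$defs": {
    "random_scalar": {
      "type": "object",
      "required": ["mean"],
      "properties": {
        "mean": {"type": "number"},
        "sd": {"type": "number", "minimum": 0},
        "lower_clip": {"type": "number"}
      }
    }
  }
}
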