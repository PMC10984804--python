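{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "xtissue pipeline report",
  "type": "object",
  "required": ["network", "communities", "trait_correlations", "opls", "provenance"],
  "properties": {
    "network": {
      "type": "object",
      "required": ["n_nodes", "n_edges", "mean_r", "modularity", "n_communities"],
      "properties": {
        "n_nodes": {"type": "integer", "minimum": 0},
        "n_edges": {"type": "integer", "minimum": 0},
        "mean_r": {"type": "number"},
        "modularity": {"type": "number", "minimum": -0.5, "maximum": 1.0},
        "n_communities": {"type": "integer", "minimum": 0}
      }
    },
    "communities": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["size", "fc_sm", "p_sm", "fc_sat", "p_sat", "p_interaction"],
        "properties": {
          "size": {"type": "integer", "minimum": 0},
          "variance_explained": {"type": "number"},
          "fc_sm": {"type": "number"},
          "p_sm": {"type": "number", "minimum": 0, "maximum": 1},
          "fc_sat": {"type": "number"},
          "p_sat": {"type": "number", "minimum": 0, "maximum": 1},
          "p_interaction": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "trait_correlations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["community", "trait", "r", "p", "n"],
        "properties": {
          "community": {},
          "trait": {"type": "string"},
          "r": {"type": "number", "minimum": -1, "maximum": 1},
          "p": {"type": "number", "minimum": 0, "maximum": 1},
          "n": {"type": "integer", "minimum": 0}
        }
      }
    },
    "opls": {"type": "object"},
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "xtissue_version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "xtissue_version": {"type": "string"}
      }
    }
  }
}
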