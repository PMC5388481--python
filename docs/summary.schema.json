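{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "barcode-eval run summary",
  "type": "object",
  "required": ["version", "seed", "model", "bootstrap_reps", "loci", "skipped"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "model": {"enum": ["p", "k2p"]},
    "bootstrap_reps": {"type": "integer", "minimum": 0},
    "skipped": {"type": "array", "items": {"type": "string"}},
    "loci": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n_sequences", "length"],
        "properties": {
          "n_sequences": {"type": "integer", "minimum": 1},
          "length": {"type": "integer", "minimum": 1},
          "locus_gap": {"type": ["boolean", "null"]},
          "excluded_specimens": {"type": "array", "items": {"type": "string"}},
          "gap_rows": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["species", "d_intra", "nearest_species",
                           "d_nn", "gap_present"],
              "properties": {
                "species": {"type": "string"},
                "d_intra": {"type": ["number", "null"]},
                "nearest_species": {"type": ["string", "null"]},
                "d_nn": {"type": ["number", "null"]},
                "gap_present": {"type": ["boolean", "null"]}
              }
            }
          },
          "monophyly": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["species", "monophyletic", "support",
                           "n_tips", "well_supported"],
              "properties": {
                "species": {"type": "string"},
                "monophyletic": {"type": "boolean"},
                "support": {"type": ["number", "null"]},
                "n_tips": {"type": "integer", "minimum": 1},
                "well_supported": {"type": "boolean"}
              }
            }
          }
        }
      }
    },
    "combinations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["loci", "arity", "shared_specimens",
                     "monophyletic_species"],
        "properties": {
          "loci": {"type": "array", "items": {"type": "string"}},
          "arity": {"enum": ["di", "tri", "tetra", "penta", "hexa"]},
          "shared_specimens": {"type": "integer", "minimum": 0},
          "monophyletic_species": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["species", "support"],
              "properties": {
                "species": {"type": "string"},
                "support": {"type": ["number", "null"]}
              }
            }
          }
        }
      }
    }
  }
}
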