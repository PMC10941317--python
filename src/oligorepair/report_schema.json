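{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Repair report",
  "description": "Per input file, the outcome of centroid selection/repair for every processed cluster.",
  "type": "object",
  "additionalProperties": {
    "type": "array",
    "items": {
      "type": "object",
      "required": ["cluster_id", "original_centroid", "chosen_sequence", "edits", "n_changes", "category"],
      "properties": {
        "cluster_id": {"type": "string"},
        "original_centroid": {"type": "string", "pattern": "^[ACGTN]*$"},
        "chosen_sequence": {"type": ["string", "null"], "pattern": "^[ACGTN]*$"},
        "edits": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["op", "position"],
            "properties": {
              "op": {"enum": ["substitution", "deletion", "insertion"]},
              "position": {"type": "integer", "minimum": 0},
              "from_base": {"type": ["string", "null"]},
              "to_base": {"type": ["string", "null"]}
            }
          }
        },
        "n_changes": {"type": "integer", "minimum": 0},
        "category": {"enum": ["correct", "substituted", "repaired", "unrecoverable"]}
      }
    }
  }
}
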