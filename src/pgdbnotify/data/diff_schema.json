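{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SnapshotDiff",
  "type": "object",
  "required": ["old_version", "new_version", "objects"],
  "properties": {
    "old_version": {"type": "string"},
    "new_version": {"type": "string"},
    "objects": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["status", "new_citations", "slots"],
        "properties": {
          "status": {"enum": ["ADDED", "REMOVED", "MODIFIED", "MERGED-AWAY"]},
          "new_citations": {"type": "array", "items": {"type": "string"}},
          "slots": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["slot", "category", "added", "removed"],
              "properties": {
                "slot": {"type": "string"},
                "category": {"type": "string"},
                "added": {"type": "array", "items": {"type": "string"}},
                "removed": {"type": "array", "items": {"type": "string"}}
              }
            }
          }
        }
      }
    }
  }
}
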