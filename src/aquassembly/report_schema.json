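{
  "type": "object",
  "required": ["provenance", "strata", "global"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package_version", "config_hash", "master_seed", "stage_seeds"],
      "properties": {
        "package_version": {"type": "string"},
        "config_hash": {"type": "string"},
        "master_seed": {"type": "integer"},
        "stage_seeds": {"type": "object"}
      }
    },
    "strata": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "n_samples": {"type": "integer"},
          "ncm": {
            "type": "object",
            "properties": {
              "nm": {"type": "number"},
              "r_squared": {"type": "number"},
              "detection_limit": {"type": "number"},
              "n_bootstrap": {"type": "integer"},
              "partition_counts": {"type": "object"}
            }
          },
          "network": {"type": "object"},
          "stability": {
            "type": "object",
            "properties": {
              "relative_modularity": {"type": "number"},
              "vulnerability": {"type": "number"}
            }
          }
        }
      }
    },
    "global": {
      "type": "object",
      "properties": {
        "permanova": {"type": "object"},
        "decay": {"type": "object"},
        "mantel": {"type": "object"},
        "env_association": {"type": "array"},
        "gene_accumulation": {"type": "array"}
      }
    }
  }
}
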