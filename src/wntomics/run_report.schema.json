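{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "wntomics pipeline run report",
  "type": "object",
  "required": ["version", "seed", "config_hash", "stages", "status"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config_hash": {"type": "string"},
    "status": {"type": "string"},
    "stages": {
      "type": "object",
      "properties": {
        "simulate": {
          "type": "object",
          "required": ["n_proteins", "n_validation_features", "n_gene_sets", "n_images", "n_cells"]
        },
        "screen": {
          "type": "object",
          "required": ["discovery_q", "in_validation", "same_direction", "top_decile_both"]
        },
        "gsea": {"type": "object", "required": ["n_sets_scored"]},
        "consistency": {"type": "object", "required": ["n_consistent"]},
        "mif": {
          "type": "object",
          "required": ["n_images_with_density", "cd8_density_mut", "cd8_density_wt", "cd8_welch_p"]
        },
        "spatial": {"type": "object", "required": ["cluster_sizes", "fisher_p"]}
      }
    }
  }
}
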