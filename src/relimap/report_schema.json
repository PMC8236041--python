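{
  "schema_version": "1",
  "required": ["schema_version", "settings", "sections"],
  "sections": ["overlap", "icc", "similarity", "conditions", "ratings"],
  "section_required_when_run": {
    "overlap": ["table", "summary", "anova", "n_undefined_pairs"],
    "icc": ["maps", "mean_icc", "cutoff", "n_above_cutoff"],
    "similarity": ["pairs"],
    "conditions": ["pairs"],
    "ratings": ["icc", "time_anova", "n_analyzed"]
  }
}
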