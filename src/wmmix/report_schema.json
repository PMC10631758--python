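{
  "type": "object",
  "required": ["config", "n_subjects", "excluded", "mixture_fits", "nearest_neighbor", "anova", "roc"],
  "properties": {
    "config": {"type": "object", "required": ["seed"], "properties": {"seed": {"type": "integer"}}},
    "n_subjects": {"type": "object"},
    "excluded": {"type": "object"},
    "mixture_fits": {"type": "object"},
    "nearest_neighbor": {"type": "object"},
    "anova": {"type": "object"},
    "roc": {"type": "object"}
  }
}
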