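{
  "type": "object",
  "required": [
    "n_pairs",
    "n_singletons",
    "seed",
    "parameters",
    "pairs_by_mode",
    "median_d_hm",
    "randomization",
    "chromosome_bias",
    "mode_tests",
    "mantel",
    "chromosome_comparison",
    "distance_correlation",
    "kaks",
    "expression",
    "functional",
    "per_mark_correlations",
    "pvalues",
    "skipped"
  ],
  "properties": {
    "n_pairs": {"type": "integer"},
    "n_singletons": {"type": "integer"},
    "seed": {"type": ["integer", "null"]},
    "parameters": {
      "type": "object",
      "required": ["n_randomizations", "mantel_permutations", "ka_max", "ks_max"],
      "properties": {
        "n_randomizations": {"type": "integer"},
        "mantel_permutations": {"type": "integer"},
        "ka_max": {"type": "number"},
        "ks_max": {"type": "number"},
        "expression_condition": {"type": "string"}
      }
    },
    "pairs_by_mode": {"type": "object"},
    "median_d_hm": {"type": "object"},
    "randomization": {"type": "object"},
    "chromosome_bias": {
      "type": ["object", "null"],
      "required": ["chi2", "df", "p"],
      "properties": {
        "chi2": {"type": "number"},
        "df": {"type": "integer"},
        "p": {"type": "number"}
      }
    },
    "mode_tests": {"type": "object"},
    "mantel": {"type": "object"},
    "chromosome_comparison": {"type": "object"},
    "distance_correlation": {"type": ["object", "null"]},
    "kaks": {"type": ["object", "null"]},
    "expression": {"type": ["object", "null"]},
    "functional": {"type": ["object", "null"]},
    "per_mark_correlations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["region", "mark", "mode", "r", "p", "n"]
      }
    },
    "pvalues": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["test", "p_raw", "p_bh"]
      }
    },
    "skipped": {"type": "object"}
  }
}
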