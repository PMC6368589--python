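{
 "type": "object",
 "required": ["seed", "config", "n_spines", "group_comparisons",
              "regression", "local_correlation", "ser", "perforation"],
 "properties": {
  "seed": {"type": "integer"},
  "config": {"type": "object"},
  "n_spines": {
   "type": "object",
   "required": ["control", "cltp", "total"],
   "properties": {
    "control": {"type": "integer"},
    "cltp": {"type": "integer"},
    "total": {"type": "integer"}
   }
  },
  "density": {
   "type": ["object", "null"],
   "required": ["brick_volume_um3", "per_sample", "t_test"],
   "properties": {
    "brick_volume_um3": {"type": "number"},
    "per_sample": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["sample_id", "condition", "density_per_um3"],
      "properties": {
       "sample_id": {"type": "string"},
       "condition": {"type": "string"},
       "density_per_um3": {"type": "number"}
      }
     }
    },
    "t_test": {
     "type": "object",
     "required": ["t", "df", "p"],
     "properties": {
      "t": {"type": "number"},
      "df": {"type": "integer"},
      "p": {"type": "number"}
     }
    }
   }
  },
  "group_comparisons": {"type": "object"},
  "regression": {"type": "object"},
  "local_correlation": {"type": "object"},
  "ser": {"type": "object"},
  "perforation": {
   "type": "object",
   "required": ["table", "perforated_without_ser"],
   "properties": {
    "table": {"type": "object"},
    "perforated_without_ser": {"type": "object"}
   }
  }
 }
}
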