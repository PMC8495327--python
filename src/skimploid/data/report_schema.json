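{
  "title": "skimploid run report",
  "required": {
    "seed": "integer",
    "parameters": "object",
    "samples": "array",
    "diploids": "array",
    "polyploids": "array",
    "bin_counts": "object",
    "repeats": "object",
    "satellites": "object",
    "trees": "object",
    "distance_matrices": "object",
    "rf_matrix": "object",
    "topology_labels": "object",
    "maternal_calls": "object",
    "dated_tree": "string_or_null",
    "provenance": "object"
  }
}
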