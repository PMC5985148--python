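{
  "description": "Required structure of a canalize run report.",
  "required": {
    "meta": {
      "package": "string",
      "version": "string",
      "timestamp": "string"
    },
    "config": {
      "seed": "number",
      "threshold": "number",
      "timescale_preset": "string",
      "parameterization": "string"
    },
    "warnings": "array",
    "analysis": {
      "validation": {
        "n_species": "number",
        "n_specimens": "number",
        "per_period": "array",
        "violations": "array"
      },
      "n_species_filtered": "number",
      "n_specimens_filtered": "number",
      "invariant_fraction_filtered": "number",
      "max_cv": "number",
      "bin_series": "array",
      "mode_comparison": "array",
      "disparity": "array",
      "trends": "array"
    }
  }
}
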