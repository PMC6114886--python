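{
  "comment": "Published group-mean pretest probabilities by stratum, model and obstructive-CAD status, from which the integrated discrimination improvement decomposes.",
  "0 RF": {
    "old": {"mean_pos": 0.44, "mean_neg": 0.18},
    "new": {"mean_pos": 0.46, "mean_neg": 0.15}
  },
  "1 RF": {
    "old": {"mean_pos": 0.48, "mean_neg": 0.22},
    "new": {"mean_pos": 0.55, "mean_neg": 0.21}
  }
}
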