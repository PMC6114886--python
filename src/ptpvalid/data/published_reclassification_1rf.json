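{
  "stratum": "1 RF",
  "comment": "Published reclassification counts for the one-risk-factor validation stratum: cross-classification of guideline PTP categories (<15%, 15-85%, >85%) under the calcium-extended model (rows) versus the clinical score (columns), split by obstructive-CAD status.",
  "categories": ["low", "medium", "high"],
  "rows": "new_model_category",
  "columns": "old_model_category",
  "counts_neg": [[418, 592, 11], [252, 410, 32], [15, 26, 5]],
  "counts_pos": [[19, 46, 5], [11, 439, 24], [3, 72, 35]]
}
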