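{
  "stratum": "0 RF",
  "comment": "Published reclassification counts for the zero-risk-factor validation stratum: cross-classification of guideline PTP categories (<15%, 15-85%, >85%) under the calcium-extended model (rows) versus the clinical score (columns), split by obstructive-CAD status.",
  "categories": ["low", "medium", "high"],
  "rows": "new_model_category",
  "columns": "old_model_category",
  "counts_neg": [[300, 260, 3], [66, 196, 6], [3, 3, 1]],
  "counts_pos": [[11, 15, 5], [6, 235, 21], [1, 57, 12]]
}
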