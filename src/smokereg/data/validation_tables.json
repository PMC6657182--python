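{
  "description": "Published cross-tabulations from an external-questionnaire validation of an EHR smokers' registry (n=1,504 patients matched to a questionnaire). Rows: questionnaire (reference) categories; columns: merged-EHR categories.",
  "status": {
    "row_labels": ["current", "former", "never"],
    "col_labels": ["current", "former", "never", "smoker_temporality_unknown", "unknown"],
    "counts": [
      [160, 9, 9, 1, 68],
      [55, 31, 27, 1, 500],
      [23, 6, 80, 1, 533]
    ]
  },
  "eligibility": {
    "row_labels": ["eligible", "not_eligible", "missing_data"],
    "col_labels": ["eligible", "not_eligible", "missing_data"],
    "counts": [
      [41, 24, 264],
      [7, 124, 948],
      [6, 13, 77]
    ]
  },
  "current_smoker": {
    "comment": "74 records coded current in the semi-structured field, cross-tabulated against the NLP label.",
    "row_labels": ["current"],
    "col_labels": ["current", "former", "never", "smoker_temporality_unknown"],
    "counts": [
      [52, 6, 15, 1]
    ]
  }
}
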