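{
  "error": 0.05882352941176472,
  "n_contigs": 16,
  "chrom_assignment_pct": 96.96969696969697,
  "ordered_pct": 90.9090909090909,
  "rank_error_mean": 0.03125,
  "rank_error_median": 0.0,
  "iqr_contigs": NaN
}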