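# Default per-metric scoring standards, keyed by instrument class then
# metric_id.  `best` is the value at/beyond which the score is 5, `worst`
# the value at/beyond which it is 1; between the two the score is linear.
# Direction comes from the intra metric registry.  These defaults were
# calibrated on controlled urine QC cohorts at conventional short-gradient
# DIA scale and are meant to be overridden per lab/instrument
# (see `cohortqc intra --standards`).
orbitrap:
  median_ms1_mass_accuracy: {best: 1.0, worst: 5.0}
  q_ms2: {best: 0.85, worst: 0.5}
  utilization: {best: 1.4, worst: 0.7}
  spectra_complexity: {best: 3.0, worst: 1.0}
  dup_rate: {best: 1.5, worst: 4.5}
  n_acquired_ms2: {best: 30000, worst: 10000}
  n_ms1_scans: {best: 1500, worst: 500}
  n_ms2_scans: {best: 30000, worst: 10000}
  n_precursors: {best: 35000, worst: 10000}
  n_peptides: {best: 25000, worst: 8000}
  n_protein_groups: {best: 3500, worst: 1500}
  missed_cleavage_rate: {best: 10.0, worst: 40.0}
  median_peak_width: {best: 0.3, worst: 1.0}
  median_fwhm: {best: 0.15, worst: 0.5}
  lc_delay_time: {best: 2.0, worst: 12.0}
  lc_tail_time: {best: 2.0, worst: 10.0}
  active_gradient_fraction: {best: 0.9, worst: 0.5}
  median_cycle_time: {best: 1.5, worst: 4.0}
  median_injection_time_ms1: {best: 20.0, worst: 100.0}
  median_injection_time_ms2: {best: 20.0, worst: 100.0}
  fraction_scans_at_max_fill: {best: 0.2, worst: 0.8}
  median_peak_count_ms1: {best: 2000, worst: 200}
  median_peak_count_ms2: {best: 300, worst: 30}
  median_base_peak_intensity_ms1: {best: 7.0, worst: 5.0}
  median_base_peak_intensity_ms2: {best: 5.5, worst: 3.5}
  tic_cv: {best: 30.0, worst: 150.0}
  tic_jump_count: {best: 0.0, worst: 20.0}
  window_load_imbalance: {best: 2.0, worst: 10.0}
  median_log10_precursor_intensity: {best: 4.5, worst: 3.0}
  intensity_dynamic_range: {best: 4.0, worst: 2.0}
  identified_feature_fraction: {best: 0.5, worst: 0.1}
  mean_protein_sequence_coverage: {best: 30.0, worst: 10.0}
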