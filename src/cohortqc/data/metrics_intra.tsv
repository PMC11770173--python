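metric_id	category	factor	unit	direction	description
n_ms1_scans	ms_signal	acquired_ms2	count	higher_is_better	Number of MS1 scans acquired in the run
n_ms2_scans	ms_signal	acquired_ms2	count	higher_is_better	Number of MS2 scans acquired in the run
median_cycle_time	ms_signal	acquired_ms2	s	lower_is_better	Median time between consecutive MS1 scans
median_injection_time_ms1	ms_signal	q_ms2	ms	lower_is_better	Median MS1 ion injection time
median_injection_time_ms2	ms_signal	q_ms2	ms	lower_is_better	Median MS2 ion injection time
fraction_scans_at_max_fill	ms_signal	q_ms2	fraction	lower_is_better	Fraction of scans whose injection time is within 1% of the run maximum (fill-time saturation)
median_peak_count_ms1	ms_signal	q_ms2	count	higher_is_better	Median number of centroid peaks per MS1 scan
median_peak_count_ms2	ms_signal	q_ms2	count	higher_is_better	Median number of centroid peaks per MS2 scan
median_base_peak_intensity_ms1	ms_signal	q_ms2	log10	higher_is_better	Median MS1 base-peak intensity (log10)
median_base_peak_intensity_ms2	ms_signal	q_ms2	log10	higher_is_better	Median MS2 base-peak intensity (log10)
identified_feature_fraction	ms_signal	q_ms2	fraction	higher_is_better	Fraction of detected MS1 features matched by an identified precursor
tic_cv	ion_source	q_ms2	%	lower_is_better	Coefficient of variation of MS1 total ion current (spray stability)
tic_jump_count	ion_source	q_ms2	count	lower_is_better	Number of adjacent-MS1 TIC jumps beyond 10-fold (spray dropouts/surges)
missed_cleavage_rate	sample	q_ms2	%	lower_is_better	Percentage of identified precursors with at least one missed cleavage
lc_delay_time	chromatography	q_ms2	min	lower_is_better	Invalid acquisition time before identifiable analytes elute
lc_tail_time	chromatography	q_ms2	min	lower_is_better	Invalid acquisition time after the last identifiable analytes elute
active_gradient_fraction	chromatography	q_ms2	fraction	higher_is_better	Fraction of the gradient carrying identifications
median_peak_width	chromatography	dup_rate	min	lower_is_better	Median chromatographic base peak width of identified precursors
median_fwhm	chromatography	dup_rate	min	lower_is_better	Median chromatographic peak full width at half maximum
n_windows_per_cycle	dia_windows	spectra_complexity	count	none	Number of MS2 isolation windows per DIA cycle
mean_window_width	dia_windows	spectra_complexity	Th	none	Mean isolation window width
window_load_imbalance	dia_windows	spectra_complexity	ratio	lower_is_better	Max/median precursors assigned per isolation window
n_acquired_ms2	identification	acquired_ms2	count	higher_is_better	Number of acquired MS2 scans
q_ms2	identification	q_ms2	fraction	higher_is_better	Identification rate of MS2 scans (identified / acquired)
spectra_complexity	identification	spectra_complexity	ratio	higher_is_better	Redundant identified precursors per identified MS2 scan
dup_rate	identification	dup_rate	ratio	lower_is_better	Redundant identified precursors per unique precursor
utilization	identification	identified_precursors	ratio	higher_is_better	Utilization rate of MS2 scans (unique precursors per identified MS2 scan)
n_precursors	identification	identified_precursors	count	higher_is_better	Number of identified peptide precursors
n_peptides	identification	identified_precursors	count	higher_is_better	Number of identified peptide sequences
n_protein_groups	identification	identified_precursors	count	higher_is_better	Number of identified protein groups
median_ms1_mass_accuracy	identification	q_ms2	ppm	lower_is_better	Median absolute delta between measured and theoretical precursor m/z
median_log10_precursor_intensity	identification	q_ms2	log10	higher_is_better	Median identified precursor intensity (log10)
intensity_dynamic_range	identification	identified_precursors	log10	higher_is_better	log10 of the p99/p1 protein-group intensity ratio
mean_protein_sequence_coverage	identification	identified_precursors	%	higher_is_better	Mean protein sequence coverage (requires a sequence database)
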