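metric_id	category	level	statistic	unit	direction	description
SP1	sample_preparation	protein	contaminant_fraction	fraction	bad_high	Summed erythrocyte-panel protein intensity over total protein intensity
SP2	sample_preparation	protein	contaminant_fraction	fraction	bad_high	Summed cellular-debris-panel protein intensity over total protein intensity
SP3	sample_preparation	protein	contaminant_fraction	fraction	bad_high	Summed serum-high-abundance-panel protein intensity over total protein intensity
LC1	liquid_chromatography	precursor	median_abs_delta_rt	min	bad_high	Median absolute deviation between empirical and calibrated precursor RT
LC2	liquid_chromatography	precursor	mean_rt_mse	min^2	bad_high	Mean of the run's pairwise RT mean-squared-error row
MS1	precursor_quant	precursor	count	count	bad_low	Number of identified precursors
MS2	precursor_quant	precursor	median_log2	log2	bad_low	Median log2 precursor intensity
MS3	precursor_quant	precursor	iqr_log2	log2	bad_high	Interquartile range of log2 precursor intensity
MS4	precursor_quant	precursor	robust_sd_log2	log2	bad_high	Robust SD (1.4826 x MAD) of log2 precursor intensity
MS5	precursor_quant	precursor	median_pearson	r	bad_low	Median pairwise Pearson correlation of log2 precursor intensity vs other runs
MS6	precursor_quant	precursor	norm_factor_log2	log2	bad_abs	Additive log2 shift applied by median normalization
MS7	peptide_quant	peptide	count	count	bad_low	Number of identified peptides
MS8	peptide_quant	peptide	median_log2	log2	bad_low	Median log2 peptide intensity
MS9	peptide_quant	peptide	iqr_log2	log2	bad_high	Interquartile range of log2 peptide intensity
MS10	peptide_quant	peptide	robust_sd_log2	log2	bad_high	Robust SD (1.4826 x MAD) of log2 peptide intensity
MS11	peptide_quant	peptide	median_pearson	r	bad_low	Median pairwise Pearson correlation of log2 peptide intensity vs other runs
MS12	peptide_quant	peptide	norm_factor_log2	log2	bad_abs	Additive log2 shift applied by median normalization
MS13	protein_quant	protein	count	count	bad_low	Number of identified protein groups
MS14	protein_quant	protein	median_log2	log2	bad_low	Median log2 protein-group intensity
MS15	protein_quant	protein	iqr_log2	log2	bad_high	Interquartile range of log2 protein-group intensity
MS16	protein_quant	protein	robust_sd_log2	log2	bad_high	Robust SD (1.4826 x MAD) of log2 protein-group intensity
MS17	protein_quant	protein	median_pearson	r	bad_low	Median pairwise Pearson correlation of log2 protein-group intensity vs other runs
MS18	protein_quant	protein	norm_factor_log2	log2	bad_abs	Additive log2 shift applied by median normalization
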