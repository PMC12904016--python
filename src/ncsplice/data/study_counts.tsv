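name	value
curated_total	2404
class_frameshift	326
class_intronic	40
class_nonframeshift	47
class_missense	1486
class_canonical_splicing	120
class_start_loss	5
class_stop_gain	333
class_stop_loss	5
class_synonymous	37
class_utr	4
prioritized_total	185
prioritized_intronic	18
prioritized_missense	35
prioritized_canonical	112
prioritized_stop_gain	12
prioritized_synonymous	8
prioritized_both_arms	132
prior_ncsv_total	32
prior_ncsv_predicted	9
prior_ncsv_validated	23
minigene_tested_reported	48
positive_reported_total	28
positive_reported_new	26
cohort_size	718
cohort_sanger_patients	34
cohort_inheritance_confirmed	17
cohort_potential_ncsv	18
cohort_minigene_tested	17
cohort_minigene_positive	12
cohort_positive_ncsv	13
cohort_positive_patients	12
positives_total	41
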