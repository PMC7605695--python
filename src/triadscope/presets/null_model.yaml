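# Structureless baseline: no reciprocity, homophily or closure effects and no
# rural/urban risk gradient. Useful for calibration of the inferential layer.
n_classrooms_rural: 6
n_classrooms_urban: 4
class_sizes_rural: [17, 17, 17, 17, 16, 16]
class_sizes_urban: [24, 24, 24, 23]
p_female: 0.54
base_tie_prob: 0.12
reciprocity_boost: 0.0
homophily_boost: 0.0
closure_prob: 0.0
closure_sweeps: 0
intensity_cuts: [0.45, 0.75, 0.92]
risk_prevalence: 0.41
risk_setting_effect: 0.0
drink_tie_prob_both_risk: 0.05
drink_tie_prob_otherwise: 0.05
audit_threshold: 8
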