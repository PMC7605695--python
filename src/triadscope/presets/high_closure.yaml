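# Strongly clustered variant: aggressive triadic closure, otherwise paper-shaped.
n_classrooms_rural: 6
n_classrooms_urban: 4
class_sizes_rural: [17, 17, 17, 17, 16, 16]
class_sizes_urban: [24, 24, 24, 23]
p_female: 0.54
base_tie_prob: 0.12
reciprocity_boost: 0.35
homophily_boost: 0.15
closure_prob: 0.6
closure_sweeps: 3
intensity_cuts: [0.45, 0.75, 0.92]
risk_prevalence: 0.41
risk_setting_effect: 0.05
drink_tie_prob_both_risk: 0.70
drink_tie_prob_otherwise: 0.15
audit_threshold: 8
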