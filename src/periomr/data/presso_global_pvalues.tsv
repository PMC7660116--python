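outcome	p_global
coronary_artery_disease	0.12
any_stroke	0.83
ischaemic_stroke	0.77
large_artery_stroke	0.50
cardioembolic_stroke	0.79
small_vessel_stroke	0.53
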