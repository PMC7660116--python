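outcome	model	variant_id	studentised_residual	cooks_distance	cd_censored
coronary_artery_disease	IVW	rs1537415	-1.24	1.55	false
coronary_artery_disease	IVW	rs4284742	-0.28	0.02	false
coronary_artery_disease	IVW	rs2738058	2.32	0.48	false
coronary_artery_disease	IVW	rs16870060	0.92	0.08	false
coronary_artery_disease	IVW	rs729876	-0.51	0.03	false
coronary_artery_disease	MR-Egger	rs1537415	-0.56	2.88	false
coronary_artery_disease	MR-Egger	rs4284742	-0.50	0.04	false
coronary_artery_disease	MR-Egger	rs2738058	1.50	0.56	false
coronary_artery_disease	MR-Egger	rs16870060	0.78	0.04	false
coronary_artery_disease	MR-Egger	rs729876	-1.70	0.48	false
any_stroke	IVW	rs1537415	-0.08	0.01	false
any_stroke	IVW	rs4284742	0.44	0.04	false
any_stroke	IVW	rs2738058	1.37	0.31	false
any_stroke	IVW	rs16870060	-0.66	0.05	false
any_stroke	IVW	rs729876	-1.93	0.18	false
any_stroke	MR-Egger	rs1537415	-0.39	1.44	false
any_stroke	MR-Egger	rs4284742	0.39	0.03	false
any_stroke	MR-Egger	rs2738058	1.80	0.69	false
any_stroke	MR-Egger	rs16870060	-0.53	0.02	false
any_stroke	MR-Egger	rs729876	-2.33	0.60	false
ischaemic_stroke	IVW	rs1537415	-1.11	1.25	false
ischaemic_stroke	IVW	rs4284742	0.06	0.005	true
ischaemic_stroke	IVW	rs2738058	2.94	0.61	false
ischaemic_stroke	IVW	rs16870060	-0.89	0.08	false
ischaemic_stroke	IVW	rs729876	0.42	0.02	false
ischaemic_stroke	MR-Egger	rs1537415	0.80	4.93	false
ischaemic_stroke	MR-Egger	rs4284742	-0.28	0.01	false
ischaemic_stroke	MR-Egger	rs2738058	1.88	0.72	false
ischaemic_stroke	MR-Egger	rs16870060	-1.72	0.09	false
ischaemic_stroke	MR-Egger	rs729876	-0.40	0.06	false
large_artery_stroke	IVW	rs1537415	-2.34	2.76	false
large_artery_stroke	IVW	rs4284742	0.73	0.11	false
large_artery_stroke	IVW	rs2738058	0.46	0.06	false
large_artery_stroke	IVW	rs16870060	1.85	0.18	false
large_artery_stroke	IVW	rs729876	-0.22	0.01	false
large_artery_stroke	MR-Egger	rs1537415	-3.42	17.59	false
large_artery_stroke	MR-Egger	rs4284742	0.48	0.04	false
large_artery_stroke	MR-Egger	rs2738058	-0.11	0.01	false
large_artery_stroke	MR-Egger	rs16870060	2.01	0.10	false
large_artery_stroke	MR-Egger	rs729876	-1.09	0.29	false
cardioembolic_stroke	IVW	rs1537415	-1.37	1.72	false
cardioembolic_stroke	IVW	rs4284742	-0.04	0.005	true
cardioembolic_stroke	IVW	rs2738058	1.33	0.30	false
cardioembolic_stroke	IVW	rs16870060	-0.56	0.03	false
cardioembolic_stroke	IVW	rs729876	1.58	0.14	false
cardioembolic_stroke	MR-Egger	rs1537415	4.32	19.31	false
cardioembolic_stroke	MR-Egger	rs4284742	-0.71	0.07	false
cardioembolic_stroke	MR-Egger	rs2738058	0.42	0.10	false
cardioembolic_stroke	MR-Egger	rs16870060	-1.86	0.10	false
cardioembolic_stroke	MR-Egger	rs729876	0.80	0.19	false
small_vessel_stroke	IVW	rs1537415	0.28	0.11	false
small_vessel_stroke	IVW	rs4284742	-4.47	0.64	false
small_vessel_stroke	IVW	rs2738058	1.04	0.22	false
small_vessel_stroke	IVW	rs16870060	0.33	0.01	false
small_vessel_stroke	IVW	rs729876	0.10	0.005	true
small_vessel_stroke	MR-Egger	rs1537415	0.85	5.59	false
small_vessel_stroke	MR-Egger	rs4284742	-5.34	0.35	false
small_vessel_stroke	MR-Egger	rs2738058	1.05	0.41	false
small_vessel_stroke	MR-Egger	rs16870060	0.27	0.005	true
small_vessel_stroke	MR-Egger	rs729876	0.06	0.005	true
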