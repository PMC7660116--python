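variant_id	locus	nearest_gene	effect_allele	other_allele	eaf	or_point	or_ci_low	or_ci_high	p_value	pve_pct	replicated
rs1537415	9q34.3	GLT6D1	C	G	0.41	1.59	1.36	1.86	5.51e-09	1.88	true
rs4284742	19q13.41	SIGLEC5	G	A	0.76	1.34	1.21	1.48	1.34e-08	0.31	true
rs2738058	8p23.1	DEFA1A3	T	C	0.43	1.28	1.18	1.38	6.78e-10	0.35	true
rs16870060	8q22.3	MTND1P5	G	T	0.91	1.36	1.23	1.51	3.69e-09	0.28	true
rs729876	16p13.12	LOC107984137	T	C	0.82	1.24	1.15	1.34	9.77e-09	0.25	true
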