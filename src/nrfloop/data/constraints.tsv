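id	system	condition	readout	target	tol	weight	cmp
hc_mA_4h	human_cell	WT	rel_mA(4)	0.41	0.10	1	eq
hc_mN_4h	human_cell	WT	rel_mN(4)	1.94	0.10	1	eq
hc_peak_L	human_cell	WT	peak_rel_L	5.0	0.10	1	eq
hc_basal_A_siNRF2	human_cell	siNRF2	basal_A_ratio	7.0	0.10	1	eq
hc_peak_A_lo	human_cell	WT	peak_rel_A	4.0	0.10	1	ge
hc_peak_A_hi	human_cell	WT	peak_rel_A	9.0	0.10	1	le
hc_L_return_4h	human_cell	WT	rel_L(4)	1.5	0.10	1	le
wm_L_3h_WT	worm	WT	rel_L(3)	0.20	0.25	1	eq
wm_L_3h_aak2	worm	aak2_null	rel_L(3)	0.60	0.0833	1	eq
wm_L_3h_skn1	worm	skn1_RNAi	rel_L(3)	0.67	0.0746	1	eq
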