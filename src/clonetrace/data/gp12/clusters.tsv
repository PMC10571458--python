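cluster	parent	n_snv	n_sbs1	n_td	ccf_1-RMidApicalCA	ccf_2-LMidApicalCA	ccf_3-LApexCA	ccf_4-RBaseCA	ccf_5-LBaseCA	ccf_6-RApexCA	ccf_7-RSVBase	ccf_8-LSVBase	ccf_RPelvicLNMet1	ccf_RPelvicLNMet2	ccf_LPelvicLNMet
T		850	150	0	1	1	1	1	1	1	1	1	1	1	1
A	T	70	12	0	0.45	0.5	0.2	0	0	0	0	0	0	0	0
B	T	80	14	0	0	0	0.4	0	0	0	0	0	0	0	0.04
C	T	60	10	0	0.4	0.3	0.28	0.85	0.9	0.8	0.95	0.92	1	1	0.96
D	T	45	8	0	0	0	0	0.1	0	0.15	0	0	0	0	0
Cb	C	85	15	0	0	0	0	0.3	0.55	0.2	0.95	0.92	1	1	0.96
Cba	Cb	55	10	0	0	0	0	0.25	0	0	0.9	0	1	1	0
Cba2	Cba	70	12	0	0	0	0	0	0	0	0.6	0	0.92	0.88	0
Cba2a	Cba2	45	8	0	0	0	0	0	0	0	0	0	0.3	0	0
Cba2b	Cba2	40	7	0	0	0	0	0	0	0	0	0	0	0.25	0
Cbb	Cb	65	11	0	0	0	0	0	0.5	0	0	0.85	0	0	0.4
Cbb2	Cbb	35	6	0	0	0	0	0	0	0	0	0.2	0	0	0.04
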