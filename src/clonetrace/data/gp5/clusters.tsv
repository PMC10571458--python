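cluster	parent	n_snv	n_sbs1	n_td	ccf_1-RApexCA	ccf_2-LApexCA	ccf_3-RCA1	ccf_4-RCA2	ccf_5-RCA3	ccf_6-LCA1	ccf_7-LCA2	ccf_8-LCA3	ccf_LPelvicLNMet1	ccf_LPelvicLNMet2	ccf_RPelvicLNMet1
T		900	160	80	1	1	1	1	1	1	1	1	1	1	1
A	T	120	20	40	0.3	0	0.85	0.9	0.88	0.15	0.1	0.92	0	0	0
Aa	A	35	6	12	0	0	0.3	0	0	0	0	0.2	0	0	0
Ab	A	50	8	16	0	0	0.4	0	0	0.1	0	0.25	0	0	0
Aba	Ab	22	4	8	0	0	0.15	0	0	0	0	0.1	0	0	0
B	T	110	18	36	0.65	0.95	0.05	0	0	0.7	0.75	0	1	1	1
Ba	B	60	10	20	0	0.55	0	0	0	0	0	0	0.14	0.16	0
Baa	Ba	28	5	10	0	0.3	0	0	0	0	0	0	0.06	0.08	0
Bb	B	70	12	24	0.12	0.1	0	0	0	0.12	0.08	0	0.86	0.84	1
Bb1	Bb	45	8	16	0	0	0	0	0	0.1	0	0	0.75	0.7	0
Bb2	Bb	55	10	20	0.1	0	0	0	0	0	0	0	0	0	1
Bc	B	20	4	8	0	0.12	0	0	0	0	0.3	0	0	0	0
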