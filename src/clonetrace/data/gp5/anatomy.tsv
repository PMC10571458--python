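sample	site_class	laterality	region
1-RApexCA	prostate	R	right apex
2-LApexCA	prostate	L	left apex
3-RCA1	prostate	R	right mid
4-RCA2	prostate	R	right mid
5-RCA3	prostate	R	right mid-base
6-LCA1	prostate	L	left posterior mid-apex
7-LCA2	prostate	L	left posterior mid-apex
8-LCA3	prostate	L	left mid
LPelvicLNMet1	lymph_node	L	left pelvic lymph node 1
LPelvicLNMet2	lymph_node	L	left pelvic lymph node 2
RPelvicLNMet1	lymph_node	R	right pelvic lymph node
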