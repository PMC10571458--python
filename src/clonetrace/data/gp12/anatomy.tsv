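sample	site_class	laterality	region
1-RMidApicalCA	prostate	R	right mid-apical
2-LMidApicalCA	prostate	L	left posterior mid-apex
3-LApexCA	prostate	L	left apex
4-RBaseCA	prostate	R	right base
5-LBaseCA	prostate	L	left base
6-RApexCA	prostate	R	right apex
7-RSVBase	seminal_vesicle	R	right seminal vesicle base
8-LSVBase	seminal_vesicle	L	left seminal vesicle base
RPelvicLNMet1	lymph_node	R	right pelvic lymph node 1
RPelvicLNMet2	lymph_node	R	right pelvic lymph node 2
LPelvicLNMet	lymph_node	L	left pelvic lymph node
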