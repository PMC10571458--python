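gene	drug	interaction_type	available
CDK12	dinaciclib	inhibitor	yes
AKT1	capivasertib	inhibitor	yes
GSK3B	lithium	inhibitor	yes
PIK3CA	alpelisib	inhibitor	yes
CCND1	palbociclib	inhibitor	yes
MDM2	idasanutlin	inhibitor	no
AR	enzalutamide	antagonist	yes
AR	abiraterone	antagonist	yes
ESR1	fulvestrant	antagonist	yes
EGFR	erlotinib	inhibitor	yes
KRAS	sotorasib	inhibitor	no
MET	crizotinib	inhibitor	yes
BRAF	vemurafenib	inhibitor	yes
HRAS	tipifarnib	inhibitor	no
TP53	eprenetapopt	reactivator	no
BRCA2	olaparib	synthetic lethality	yes
PTEN	ipatasertib	pathway inhibitor	no
CDK4	palbociclib	inhibitor	yes
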