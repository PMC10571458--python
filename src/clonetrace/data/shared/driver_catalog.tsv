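gene	evidence	direction
CDK12	reported	loss
AKT1	reported	gain
GSK3B	candidate	gain
PIK3CA	reported	gain
CCND1	reported	gain
MDM2	reported	gain
MYC	reported	gain
RB1	reported	loss
CHD1	reported	loss
NKX3-1	reported	loss
ZBTB16	candidate	loss
FOXA1	reported	gain
TP53	reported	loss
PTEN	reported	loss
SPOP	reported	loss
ATM	reported	loss
ERF	candidate	loss
KMT2C	reported	loss
NCOA2	reported	gain
CTNNB1	reported	gain
KRAS	reported	gain
BRAF	reported	gain
PIK3CB	candidate	gain
AR	reported	gain
MET	reported	gain
ESR1	candidate	gain
EGFR	reported	gain
TMPRSS2	reported	gain
KDM6A	reported	loss
ZMYM3	candidate	loss
APC	reported	loss
KMT2D	reported	loss
CDKN1B	reported	loss
BRCA2	reported	loss
HRAS	reported	gain
GNAS	candidate	gain
CDK4	reported	gain
MED12	candidate	loss
ZFHX3	reported	loss
ETV1	reported	gain
BRIP1	candidate	unknown
USP28	candidate	unknown
SALL4	candidate	unknown
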