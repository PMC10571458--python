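gene	cluster	kind	effect	variant_class
PTEN	T	CNA	loss-of-function	homozygous_loss
CDKN1B	T	CNA	loss-of-function	homozygous_loss
BRCA2	T	CNA	loss-of-function	het_loss
BRCA2	T	SNV	loss-of-function	protein_altering
ETV1	T	SV	gain-of-function	fusion
TP53	T	SNV	loss-of-function	protein_altering
SPOP	T	SNV	loss-of-function	protein_altering
FOXA1	T	SNV	gain-of-function	protein_altering
CHD1	T	CNA	loss-of-function	homozygous_loss
RB1	T	CNA	loss-of-function	het_loss
MYC	T	CNA	gain-of-function	copy_gain
NKX3-1	T	CNA	loss-of-function	het_loss
ZBTB16	T	CNA	loss-of-function	het_loss
APC	T	SNV	loss-of-function	protein_altering
ATM	A	SNV	loss-of-function	protein_altering
KDM6A	B	SNV	loss-of-function	protein_altering
ERF	C	SNV	loss-of-function	protein_altering
ZFHX3	D	SNV	loss-of-function	protein_altering
AR	Cb	CNA	gain-of-function	copy_gain
KMT2C	Cb	SNV	loss-of-function	protein_altering
CTNNB1	Cb	SNV	gain-of-function	protein_altering
HRAS	Cba	SNV	gain-of-function	protein_altering
KRAS	Cba	SNV	gain-of-function	protein_altering
NCOA2	Cba	CNA	gain-of-function	copy_gain
BRAF	Cba2	SNV	gain-of-function	protein_altering
AKT1	Cba2	CNA	gain-of-function	copy_gain
EGFR	Cba2	CNA	gain-of-function	copy_gain
MED12	Cba2	SNV	loss-of-function	protein_altering
TP53	Cbb	CNA	loss-of-function	loh
ESR1	Cbb	SNV	gain-of-function	protein_altering
GNAS	Cbb	SNV	gain-of-function	protein_altering
PIK3CB	Cbb	CNA	gain-of-function	copy_gain
MET	Cbb2	CNA	gain-of-function	copy_gain
CDK4	Cbb2	CNA	gain-of-function	copy_gain
AR	Cba2a	CNA	gain-of-function	copy_gain
MYC	Cba2b	CNA	gain-of-function	copy_gain
BRIP1	Cba	SNV	unknown	protein_altering
USP28	D	SNV	unknown	protein_altering
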