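gene	cluster	kind	effect	variant_class
CDK12	T	SNV	loss-of-function	protein_altering
CDK12	T	CNA	loss-of-function	homozygous_loss
AKT1	T	CNA	gain-of-function	copy_gain
GSK3B	T	CNA	gain-of-function	copy_gain
PIK3CA	T	CNA	gain-of-function	copy_gain
CCND1	T	CNA	gain-of-function	copy_gain
MDM2	T	CNA	gain-of-function	copy_gain
MYC	T	CNA	gain-of-function	copy_gain
RB1	T	CNA	loss-of-function	homozygous_loss
CHD1	T	CNA	loss-of-function	homozygous_loss
NKX3-1	T	CNA	loss-of-function	homozygous_loss
ZBTB16	T	CNA	loss-of-function	homozygous_loss
FOXA1	T	SNV	gain-of-function	protein_altering
TP53	T	SNV	loss-of-function	protein_altering
PTEN	T	CNA	loss-of-function	homozygous_loss
SPOP	A	SNV	loss-of-function	protein_altering
ATM	Ab	SNV	loss-of-function	protein_altering
ERF	Aba	SNV	loss-of-function	protein_altering
KMT2C	B	SNV	loss-of-function	protein_altering
NCOA2	B	CNA	gain-of-function	copy_gain
CTNNB1	B	SNV	gain-of-function	protein_altering
KRAS	Ba	SNV	gain-of-function	protein_altering
BRAF	Ba	SNV	gain-of-function	protein_altering
PIK3CB	Ba	CNA	gain-of-function	copy_gain
AR	Baa	CNA	gain-of-function	copy_gain
MET	Baa	CNA	gain-of-function	copy_gain
AR	Bb	CNA	gain-of-function	copy_gain
ESR1	Bb	SNV	gain-of-function	protein_altering
EGFR	Bb	CNA	gain-of-function	copy_gain
TMPRSS2	Bb1	SV	gain-of-function	fusion
KDM6A	Bb1	SNV	loss-of-function	protein_altering
ZMYM3	Bb1	SNV	loss-of-function	protein_altering
APC	Bb2	SNV	loss-of-function	protein_altering
KMT2D	Bb2	SNV	loss-of-function	protein_altering
CDKN1B	Bb2	CNA	loss-of-function	homozygous_loss
BRIP1	Bc	SNV	unknown	protein_altering
USP28	Aa	SNV	unknown	protein_altering
SALL4	Ba	SNV	unknown	protein_altering
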