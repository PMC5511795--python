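symbol	subpanel	tier	bold	rearrangement_only
ABL1	somatic_snv		0	0
BRCA2	somatic_snv		0	0
CDKN2B	somatic_snv		0	0
ERBB4	somatic_snv		0	0
GNA11	somatic_snv		0	0
INPP4B	somatic_snv		0	0
MPL	somatic_snv		0	0
PIK3R2	somatic_snv		0	0
SH2B3	somatic_snv		0	0
AKT1	somatic_snv		0	0
CBL	somatic_snv		0	0
CDKN2C	somatic_snv		0	0
FANCA	somatic_snv		0	0
GNAQ	somatic_snv		0	0
JAK1	somatic_snv		0	0
MTOR	somatic_snv		0	0
POLE	somatic_snv		0	0
SMO	somatic_snv		0	0
ALK	somatic_snv		0	0
CCND1	somatic_snv		0	0
CHEK2	somatic_snv		0	0
FBXW7	somatic_snv		0	0
GNAS	somatic_snv		0	0
JAK2	somatic_snv		0	0
MYD88	somatic_snv		0	0
PRKCH	somatic_snv		0	0
SOCS1	somatic_snv		0	0
AR	somatic_snv		0	0
CCND2	somatic_snv		0	0
CSF1R	somatic_snv		0	0
FGFR1	somatic_snv		0	0
HDAC2	somatic_snv		0	0
JAK3	somatic_snv		0	0
NF1	somatic_snv		0	0
PTCH1	somatic_snv		0	0
SRC	somatic_snv		0	0
ARAF	somatic_snv		0	0
CCND3	somatic_snv		0	0
CSF3R	somatic_snv		0	0
FGFR2	somatic_snv		0	0
HGF	somatic_snv		0	0
KDR	somatic_snv		0	0
NF2	somatic_snv		0	0
PTEN	somatic_snv		0	0
STAG2	somatic_snv		0	0
ARID1A	somatic_snv		0	0
CD274	somatic_snv		0	0
CTNNB1	somatic_snv		0	0
FGFR3	somatic_snv		0	0
HRAS	somatic_snv		0	0
KIT	somatic_snv		0	0
NRAS	somatic_snv		0	0
RAC1	somatic_snv		0	0
STK11	somatic_snv		0	0
ATM	somatic_snv		0	0
CDK4	somatic_snv		0	0
DDR2	somatic_snv		0	0
FGFR4	somatic_snv		0	0
IDH1	somatic_snv		0	0
KRAS	somatic_snv		0	0
PALB2	somatic_snv		0	0
RAD51C	somatic_snv		0	0
TSC1	somatic_snv		0	0
ATR	somatic_snv		0	0
CDK6	somatic_snv		0	0
EGFR	somatic_snv		0	0
FLCN	somatic_snv		0	0
IDH2	somatic_snv		0	0
MAP2K1	somatic_snv		0	0
PDGFRA	somatic_snv		0	0
RAF1	somatic_snv		0	0
TSC2	somatic_snv		0	0
BAP1	somatic_snv		0	0
CDKN1A	somatic_snv		0	0
EPHA2	somatic_snv		0	0
FLT3	somatic_snv		0	0
IGF1R	somatic_snv		0	0
MAP2K2	somatic_snv		0	0
PIK3CA	somatic_snv		0	0
RET	somatic_snv		0	0
VEGFA	somatic_snv		0	0
BRAF	somatic_snv		0	0
CDKN1B	somatic_snv		0	0
ERBB2	somatic_snv		0	0
FRS2	somatic_snv		0	0
IGF2	somatic_snv		0	0
MET	somatic_snv		0	0
PIK3CB	somatic_snv		0	0
RICTOR	somatic_snv		0	0
BRCA1	somatic_snv		0	0
CDKN2A	somatic_snv		0	0
ERBB3	somatic_snv		0	0
GATA3	somatic_snv		0	0
IL7R	somatic_snv		0	0
MITF	somatic_snv		0	0
PIK3R1	somatic_snv		0	0
ROS1	somatic_snv		0	0
ALK	somatic_rearrangement		0	0
BCR	somatic_rearrangement		0	0
BRAF	somatic_rearrangement		0	0
ERBB4	somatic_rearrangement		0	0
FGFR2	somatic_rearrangement		0	0
FGFR3	somatic_rearrangement		0	0
JAK2	somatic_rearrangement		0	0
MET	somatic_rearrangement		0	0
NRG1	somatic_rearrangement		0	0
NTRK1	somatic_rearrangement		0	0
PDGFB	somatic_rearrangement		0	0
PDGFRA	somatic_rearrangement		0	0
RAF1	somatic_rearrangement		0	0
RET	somatic_rearrangement		0	0
ROS1	somatic_rearrangement		0	0
TFE3	somatic_rearrangement		0	0
TMPRSS2	somatic_rearrangement		0	0
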