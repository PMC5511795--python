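symbol	subpanel	tier	bold	rearrangement_only
APC	germline	1	1	0
BRIP1	germline	1	1	0
FANCA	germline	1	0	0
FANCL	germline	1	0	0
MEN1	germline	1	0	0
NF2	germline	1	0	0
PTCH1	germline	1	0	0
SDHA	germline	1	1	0
SUFU	germline	1	0	0
ATM	germline	1	1	0
CDH1	germline	1	1	0
FANCB	germline	1	0	0
FANCM	germline	1	0	0
MET	germline	1	0	0
NTHL1	germline	1	0	0
PTCH2	germline	1	0	0
SDHAF2	germline	1	1	0
TERT	germline	1	0	0
AXIN2	germline	1	0	0
CDK4	germline	1	1	0
FANCC	germline	1	0	0
FH	germline	1	0	0
MLH1	germline	1	1	0
PALB2	germline	1	1	0
PTEN	germline	1	1	0
SDHB	germline	1	1	0
TMEM127	germline	1	1	0
BAP1	germline	1	0	0
CDKN1B	germline	1	0	0
FANCD2	germline	1	0	0
FLCN	germline	1	0	0
MSH2	germline	1	1	0
PDGFRA	germline	1	0	0
RAD51C	germline	1	1	0
SDHC	germline	1	1	0
TP53	germline	1	1	0
BARD1	germline	1	0	0
CDKN2A	germline	1	1	0
FANCE	germline	1	0	0
GREM1	germline	1	0	0
MSH6	germline	1	1	0
PMS2	germline	1	1	0
RAD51D	germline	1	1	0
SDHD	germline	1	1	0
TSC1	germline	1	0	0
BMPR1A	germline	1	1	0
CHEK2	germline	1	1	0
FANCF	germline	1	0	0
KIT	germline	1	0	0
MUTYH	germline	1	1	0
POLD1	germline	1	1	0
RB1	germline	1	0	0
SLX4	germline	1	0	0
TSC2	germline	1	0	0
BRCA1	germline	1	1	0
EGFR	germline	1	0	0
FANCG	germline	1	0	0
MAX	germline	1	1	0
NBN	germline	1	1	0
POLE	germline	1	1	0
RET	germline	1	1	0
SMAD4	germline	1	1	0
UBE2T	germline	1	0	0
BRCA2	germline	1	1	0
EPCAM	germline	1	0	0
FANCI	germline	1	0	0
MC1R	germline	1	0	0
NF1	germline	1	1	0
POT1	germline	1	0	0
RHBDF2	germline	1	0	0
STK11	germline	1	1	0
VHL	germline	1	1	0
ALK	germline	2	0	0
DIS3L2	germline	2	0	0
FAH	germline	2	0	0
KHDC3L	germline	2	0	0
PHOX2B	germline	2	0	0
RPL11	germline	2	0	0
SEC23B	germline	2	0	0
SPINK1	germline	2	0	0
WT1	germline	2	0	0
BLM	germline	2	0	0
DKC1	germline	2	0	0
FAS	germline	2	0	0
KRAS	germline	2	0	0
POLH	germline	2	0	0
RPL35A	germline	2	0	0
SERPINA1	germline	2	0	0
STIM1	germline	2	0	0
XIAP	germline	2	0	0
BRAF	germline	2	0	0
ERCC1	germline	2	0	0
FASLG	germline	2	0	0
LZTR1	germline	2	0	0
PRF1	germline	2	0	0
RPL5	germline	2	0	0
SH2D1A	germline	2	0	0
TERC	germline	2	0	0
XPA	germline	2	0	0
BUB1B	germline	2	0	0
ERCC2	germline	2	0	0
GPC3	germline	2	0	0
MNX1	germline	2	0	0
PRKAR1A	germline	2	0	0
RPS19	germline	2	0	0
SHOC2	germline	2	0	0
TINF2	germline	2	0	0
XPC	germline	2	0	0
CBL	germline	2	0	0
ERCC3	germline	2	0	0
H19	germline	2	0	0
MTAP	germline	2	0	0
PRSS1	germline	2	0	0
RPS24	germline	2	0	0
SLC25A13	germline	2	0	0
TRIM37	germline	2	0	0
CDKN1C	germline	2	0	0
ERCC4	germline	2	0	0
HFE	germline	2	0	0
NHP2	germline	2	0	0
PTPN11	germline	2	0	0
RPS7	germline	2	0	0
SMARCA4	germline	2	0	0
UNC13D	germline	2	0	0
CYLD	germline	2	0	0
ERCC5	germline	2	0	0
HRAS	germline	2	0	0
NLRP7	germline	2	0	0
RAF1	germline	2	0	0
RTEL1	germline	2	0	0
SMARCB1	germline	2	0	0
WNT10A	germline	2	0	0
DDB2	germline	2	0	0
EXT1	germline	2	0	0
ITK	germline	2	0	0
NOP10	germline	2	0	0
RECQL4	germline	2	0	0
RUNX1	germline	2	0	0
SOS1	germline	2	0	0
WRAP53	germline	2	0	0
DICER1	germline	2	0	0
EXT2	germline	2	0	0
KCNQ1OT1	germline	2	0	0
NSD1	germline	2	0	0
RIT1	germline	2	0	0
SBDS	germline	2	0	0
SOS2	germline	2	0	0
WRN	germline	2	0	0
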