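symbol	subpanel	tier	bold	rearrangement_only
ATP2A2	research		0	0
DLEU7	research		0	0
GALNT12	research		0	0
KMT2C	research		0	0
PAX5	research		0	0
PTPRD	research		0	0
UNC5C	research		0	0
AXIN1	research		0	0
DNAAF1	research		0	0
GATA2	research		0	0
MAPK1	research		0	0
PBRM1	research		0	0
RECQL	research		0	0
XRCC2	research		0	0
BTK	research		0	0
EGLN1	research		0	0
HNF1A	research		0	0
MDH2	research		0	0
PDE11A	research		0	0
RNASEL	research		0	0
XRCC4	research		0	0
CDC73	research		0	0
EGLN2	research		0	0
HNF1B	research		0	0
MRE11A	research		0	0
PDPK1	research		0	0
SASH1	research		0	0
YAP1	research		0	0
CEBPA	research		0	0
ENG	research		0	0
HOXB13	research		0	0
MSR1	research		0	0
PIF1	research		0	0
SEMA4A	research		0	0
CRKL	research		0	0
EPAS1	research		0	0
HOXD4	research		0	0
NFKBIZ	research		0	0
PLCG2	research		0	0
SFXN4	research		0	0
CTNNA1	research		0	0
EPHB2	research		0	0
IL10RB	research		0	0
NOTCH1	research		0	0
PMS1	research		0	0
SLBP	research		0	0
CTR9	research		0	0
EPHX1	research		0	0
INHBA	research		0	0
NOTCH2	research		0	0
PPARG	research		0	0
SMAD9	research		0	0
CTRC	research		0	0
FAM175A	research		0	0
KIF1B	research		0	0
NTRK3	research		0	1
PRKCD	research		0	0
SRP72	research		0	0
DAPK1	research		0	0
FAN1	research		0	0
KMT2A	research		0	0
OGG1	research		0	0
PSMC3IP	research		0	0
SRY	research		0	0
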