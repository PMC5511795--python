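case_id	gene	hgvs_c	hgvs_p	zygosity	category
ONCOC.001_G	SDHD	c.34G>A	p.G12S		other_vus
ONCOC.001_G	SDHD	c.149A>G	p.H50R		other_vus
ONCOG.001	ATM	c.998C>T	p.S333F	Het.	other_vus
ONCOG.001	CDH1	c.-54G>C		Het.	other_vus
ONCOG.002	CDKN2A	c.176T>G	p.V59G	Het.	pathogenic
ONCOG.002	BRCA2	c.4258G>T	p.D1420Y	Het.	other_vus
ONCOG.002	PTCH2	c.1073G>A	p.R358H	Het.	other_vus
ONCOG.002	SUFU	c.1018G>T	p.A340S	Het.	other_vus
ONCOG.003	BRCA1	c.4883T>C	p.M1628T	Het.	other_vus
ONCOG.003	BRCA2	c.4258G>T	p.D1420Y	Het.	other_vus
ONCOG.003	FANCM	c.1667A>G	p.D556G	Het.	other_vus
ONCOG.003	PTCH2	c.1073G>A	p.R358H	Het.	other_vus
ONCOG.004	BRCA2	c.7008-62A>G		Het.	dm_controversial
ONCOG.004	CDH1	c.-54G>C		Het.	other_vus
ONCOG.004	SDHD	c.149A>G	p.H50R	Het.	other_vus
ONCOG.005	FANCA	c.3348+18A>G		Het.	dm_controversial
ONCOG.006	FANCA	c.932T>C	p.I311T	Het.	other_vus
ONCOG.006	FANCI	c.1573A>G	p.M525V	Het.	other_vus
ONCOG.006	MUTYH	c.1258C>A	p.L420M	Het.	other_vus
ONCOG.006	NF1	c.7259-17C>T		Het.	other_vus
ONCOG.007	FANCA	c.3348+18A>G		Het.	dm_controversial
ONCOG.007	ATM	c.2119T>C	p.S707P	Het.	other_vus
ONCOG.007	AXIN2	c.1685C>T	p.P562L	Het.	other_vus
ONCOG.007	BRCA1	c.2890G>A	p.G964R	Het.	other_vus
ONCOG.007	FANCB	c.2395G>A	p.A799T	Het.	other_vus
ONCOG.007	FANCD2	c.3127G>A	p.G1043S	Het.	other_vus
ONCOG.008	ATM	c.998C>T	p.S333F	Het.	other_vus
ONCOG.008	FANCM	c.5177C>T	p.P1726L	Het.	other_vus
ONCOG.009	MC1R	c.464T>C	p.I155T	Het.	dm_controversial
ONCOG.009	TSC2	c.5383C>T	p.R1795C	Het.	dm_controversial
ONCOG.009	FANCD2	c.3275A>G	p.H1092R	Het.	other_vus
ONCOG.009	POLD1	c.189G>T	p.E63D	Het.	other_vus
ONCOG.009	SLX4	c.5501A>G	p.N1834S	Het.	other_vus
ONCOG.010	FANCM	c.3857G>T	p.S1286I	Het.	other_vus
ONCOG.010	MSH6	c.*20_*24del		Het.	other_vus
ONCOG.011	KIT	c.67+4G>A		Het.	dm_controversial
ONCOG.011	PMS2	c.1688G>T	p.R563L	Het.	other_vus
ONCOG.011	SDHD	c.34G>A	p.G12S	Het.	other_vus
ONCOG.011	SUFU	c.1018G>T	p.A340S	Het.	other_vus
ONCOG.012	MLH1	c.1852_1853delAAinsGC	p.K618A	Het.	other_vus
ONCOG.012	ATM	c.2519A>T	p.D840V	Het.	other_vus
ONCOG.012	FLCN	c.979G>A	p.A327T	Het.	other_vus
ONCOG.013	ATM	c.1810C>T	p.P604S	Het.	dm_controversial
ONCOG.013	ATM	c.6067G>A	p.G2023R	Het.	other_vus
ONCOG.014	RET	c.1529C>T	p.A510V	Het.	dm_controversial
ONCOG.014	FANCA	c.3348+18A>G		Het.	dm_controversial
ONCOG.014	MET	c.504G>T	p.E168D	Het.	other_vus
ONCOG.014	SDHD	c.34G>A	p.G12S	Het.	other_vus
ONCOG.014	POLE	c.2090C>G	p.P697R	Het.	other_vus
ONCOG.014	BRCA1	c.3083G>A	p.R1028H	Het.	other_vus
ONCOG.015					none
ONCOG.016	ATM	c.1744T>C	p.F582L	Het.	dm_controversial
ONCOG.016	BARD1	c.2212A>G	p.I738V	Het.	other_vus
ONCOG.016	BMPR1A	c.478A>G	p.M160V	Het.	other_vus
ONCOG.016	CHEK2	c.254C>T	p.P85L	Het.	other_vus
ONCOG.017	FANCF	c.557C>T	p.A186V	Het.	other_vus
ONCOG.017	PALB2	c.2590C>T	p.P864S	Het.	other_vus
ONCOG.017	POLD1	c.2317G>A	p.A773T	Het.	other_vus
ONCOG.017	SUFU	c.1018G>T	p.A340S	Het.	other_vus
ONCOG.018					none
ONCOG.019	FANCA	c.3348+18A>G		Het.	dm_controversial
ONCOG.019	BRIP1	c.584T>C	p.L195P	Het.	other_vus
ONCOG.019	SLX4	c.710G>A	p.R237Q	Het.	other_vus
ONCOG.019	SLX4	c.4597G>C	p.A1533P	Het.	other_vus
ONCOG.020	ATM	c.8560C>T	p.R2854C	Het.	other_vus
ONCOG.020	EPCAM	c.488G>A	p.R163Q	Het.	other_vus
ONCOG.021	RET	c.2531G>A	p.R844Q	Het.	dm_controversial
ONCOG.021	BARD1	c.2212A>G	p.I738V	Het.	other_vus
ONCOG.021	BRIP1	c.3275C>A	p.P1092Q	Het.	other_vus
ONCOG.021	MUTYH	c.950T>C	p.L317P	Het.	other_vus
ONCOG.022	ATM	c.2572T>C	p.F858L	Het.	other_vus
ONCOG.022	FANCA	c.1870G>T	p.A624S	Het.	other_vus
ONCOG.022	FANCC	c.29G>A	p.C10Y	Het.	other_vus
ONCOG.022	PTCH2	c.1073G>A	p.R358H	Het.	other_vus
ONCOG.022	SDHD	c.34G>A	p.G12S	Het.	other_vus
ONCOG.023	FANCM	c.4005dupA	p.V1336Sfs*8	Het.	likely_pathogenic
ONCOG.023	ATM	c.2119T>C	p.S707P	Het.	other_vus
ONCOG.023	BAP1	c.1769A>T	p.Q590L	Het.	other_vus
ONCOG.023	BRCA1	c.591C>T	p.C197C	Het.	other_vus
ONCOG.023	CDH1	c.532-18C>T		Het.	other_vus
ONCOG.023	FANCC	c.77C>T	p.S26F	Het.	other_vus
ONCOG.023	PALB2	c.2590C>T	p.P864S	Het.	other_vus
ONCOG.023	PTCH1	c.505G>A	p.V169I	Het.	other_vus
ONCOG.024	NF1	c.2033dupC	p.I679Dfs*21	Mosaic	pathogenic
ONCOG.024	FANCA	c.3099C>A	p.D1033E	Het.	other_vus
ONCOG.024	BRCA1	c.3929C>A	p.T1310K	Het.	other_vus
ONCOG.025	BARD1	c.1075_1095del	p.L359_P365del	Het.	dm_controversial
ONCOG.025	cdkn2ai3	c.187G>C	p.G63R	Het.	dm_controversial
ONCOG.025	FANCM	c.3857G>T	p.S1286I	Het.	other_vus
ONCOG.025	MC1R	c.252C>A	p.D84E	Het.	other_vus
ONCOG.025	PALB2	c.2590C>T	p.P864S	Het.	other_vus
ONCOG.025	PALB2	c.232G>A	p.V78I	Het.	other_vus
ONCOG.026	FANCA	c.3099C>A	p.D1033E	Het.	other_vus
ONCOG.027	BRCA1	c.3708T>G	p.N1236K	Het.	other_vus
ONCOG.027	FANCC	c.584A>T	p.D195V	Het.	other_vus
ONCOG.027	FANCI	c.3812C>T	p.S1271F	Het.	other_vus
ONCOG.027	FANCM	c.4931G>A	p.R1644Q	Het.	other_vus
ONCOG.027	MSH6	c.100G>T	p.A34S	Het.	other_vus
ONCOG.028	SLX4	c.421G>T	p.G141W	Het.	dm_controversial
ONCOG.028	BRCA2	c.68-7T>A		Het.	other_vus
ONCOG.029	MET	c.504G>T	p.E168D	Het.	other_vus
ONCOG.029	SDHD	c.149A>G	p.H50R	Het.	other_vus
ONCOG.030	ATM	c.1810C>T	p.P604S	Het.	dm_controversial
ONCOG.030	BRCA1	c.4039A>G	p.R1347G	Het.	other_vus
ONCOG.030	TSC2	c.1577G>A	p.S526N	Het.	other_vus
ONCOG.031	FANCA	c.4069_4082del	p.A1357Lfs*63	Het.	dm_controversial
ONCOG.031	FANCM	c.171G>C	p.L57F	Het.	other_vus
ONCOG.031	RET	c.166C>A	p.L56M	Het.	other_vus
ONCOG.032	FANCL	c.1051_1052delAG	p.S351Ffs*2	Het.	likely_pathogenic
ONCOG.032	BARD1	c.1028C>T	p.T343I	Het.	other_vus
ONCOG.032	NBN	c.1591A>G	p.I531V	Het.	other_vus
ONCOG.032	PTCH1	c.1306G>A	p.D426N	Het.	other_vus
ONCOG.033	BRCA2	c.2806_2809del	p.A938Pfs*21	Het.	pathogenic
ONCOG.033	FANCA	c.1874G>C	p.C625S	Het.	dm_controversial
ONCOG.034	APC	c.4424C>T	p.A1475V	Het.	other_vus
ONCOG.034	TMEM127	c.221A>G	p.Y74C	Het.	other_vus
ONCOG.035	VHL	c.269A>G	p.N90S		other_vus
ONCOG.035	APC	c.3949G>C	p.E1317Q		other_vus
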