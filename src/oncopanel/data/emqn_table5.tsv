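sample	gene	hgvs_c	hgvs_p	ddpcr_pct	ngs_pct
1	BRAF	c.1799T>A	p.V600E	16	19.24
1	KRAS	c.38G>A	p.G13D	16	16.97
1	PIK3CA	c.3140A>G	p.H1047R	17	15.12
2	BRAF	c.1799T>A	p.V600E	66.7	67.62
2	EGFR	c.2155G>A	p.G719S	1.1	0.72
2	EGFR	c.2235_2249del15	p.E746_A750del	0.9	0.28
2	EGFR	c.2369C>T	p.T790M	1.2	2.11
2	EGFR	c.2573T>G	p.L858R	1.3	0.95
2	EGFR	c.2582T>A	p.L861Q	0.7	0.95
2	PIK3CA	c.3140A>G	p.H1047R	50	46.87
3	BRAF	c.1799T>A	p.V600E	12	12.88
3	EGFR	c.2155G>A	p.G719S	23.6	22.44
3	EGFR	c.2235_2249del15	p.E746_A750del	1.7	0.72
3	EGFR	c.2369C>T	p.T790M	1.02	1.33
3	EGFR	c.2573T>G	p.L858R	3.4	3.82
3	KIT	c.2447A>T	p.D816V	9	9.75
3	KRAS	c.35G>A	p.G12D	5.9	7.97
3	KRAS	c.38G>A	p.G13D	15	13.55
3	NRAS	c.181C>A	p.Q61K	12	8.55
3	PIK3CA	c.1633G>A	p.E545K	7.8	9.98
3	PIK3CA	c.3140A>G	p.H1047R	18	18.36
4	BRAF	c.1799T>A	p.V600E	9.4	4.09
4	EGFR	c.2155G>A	p.G719S	26.5	15.87
4	EGFR	c.2235_2249del15	p.E746_A750del	2.3	1.5
4	EGFR	c.2369C>T	p.T790M	0.85	0.9
4	EGFR	c.2573T>G	p.L858R	2.4	1.2
4	KIT	c.2447A>T	p.D816V	9	15.79
4	KRAS	c.35G>A	p.G12D	5.5	11.81
4	KRAS	c.38G>A	p.G13D	16	16.79
4	NRAS	c.181C>A	p.Q61K	10	8.84
4	PIK3CA	c.1633G>A	p.E545K	7.6	4.32
4	PIK3CA	c.3140A>G	p.H1047R	20	25
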