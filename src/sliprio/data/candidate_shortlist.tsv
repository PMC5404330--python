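chrom	pos	rsid	ref	alt	carriers	freq_evs_pct	freq_kg_pct	gene	func_class	coding_change	phylop	phastcons	sift	polyphen	segdup	min_depth
chr2	125504881	rs35085748	T	C	39	0.78	0.64	CNTNAP5	nonsynonymous_snv	NM_130773:exon14:c.T2150C:p.V717A	1.27	0.93	0.59	0.0	0	35
chr3	78766524	rs80030397	A	G	17	0.02	0.05	ROBO1	nonsynonymous_snv	NM_001145845:exon5:c.T701C:p.V234A	4.77	1.0	0.17	1.0	0	35
chr7	69364311	rs142957106	C	T	19	0.08	NA	AUTS2	nonsynonymous_snv	NM_001127231:exon2:c.C349T:p.R117C	2.84	1.0	0.02	1.0	0	35
chr7	146829358	rs368057493	G	T	40	NA	NA	CNTNAP2	nonsynonymous_snv	NM_014141:exon8:c.G1105T:p.V369L	5.44	1.0	0.35	0.0	0	35
chr12	1137072	.	G	A	23	NA	NA	ERC1	nonsynonymous_snv	NM_178039:exon2:c.G3A:p.M1I	6.15	1.0	0.0	0.91	0	35
chr12	13715865	.	C	G	25	NA	NA	GRIN2B	nonsynonymous_snv	NM_000834:exon13:c.G4307C:p.G1436A	1.29	1.0	0.9	0.0	0	35
chr15	48063365	.	C	G	30	NA	NA	SEMA6D	nonsynonymous_snv	NM_020858:exon17:c.C2419G:p.H807D	5.7	1.0	0.26	0.49	0	35
chr16	9916226	.	C	G	4	NA	NA	GRIN2A	nonsynonymous_snv	NM_001134407:exon10:c.G2063C:p.G688A	5.94	1.0	0.0	1.0	0	35
chr16	84438827	rs78887288	G	A	35	0.46	0.14	ATP2C2	nonsynonymous_snv	NM_001286527:exon3:c.G304A:p.V102M	0.24	0.09	0.11	0.03	0	35
chr16	84494315	rs62050917	C	T	27,36,39	0.79	0.41	ATP2C2	nonsynonymous_snv	NM_001291454:exon21:c.C1936T:p.R646W	-1.51	0.0	0.0	0.99	0	35
chrX	99922289	rs121918363	A	G	41	0.08	NA	SRPX2	nonsynonymous_snv	NM_014467:exon9:c.A980G:p.N327S	1.37	0.92	0.0	0.06	0	35
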