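chrom	pos	rsid	ref	alt	carriers	freq_evs_pct	freq_kg_pct	gene	func_class	coding_change	phylop	phastcons	sift	polyphen	segdup	min_depth
chr2	32689842	rs61754195	C	T	26,42	0.98	0.46	BIRC6	nonsynonymous_snv	NM_016252:exon25:c.C5207T:p.P1736L	3.09	0.99	0.01	0.6	0	35
chr2	32740353	rs61757638	C	T	26,42	0.25	0.18	BIRC6	nonsynonymous_snv	NM_016252:exon55:c.C10865T:p.A3622V	6.06	1.0	0.0	0.99	0	35
chr2	167089942	rs180922748	G	C	2	0.2	0.14	SCN9A	nonsynonymous_snv	NM_002977:exon21:c.C3799G:p.L1267V	2.07	1.0	0.13	0.99	0	35
chr2	167094638	rs141268327	T	C	2	0.53	0.41	SCN9A	nonsynonymous_snv	NM_002977:exon20:c.A3734G:p.N1245S	4.93	1.0	0.0	1.0	0	35
chr3	58104626	rs139875974	G	T	40	0.07	0.05	FLNB	nonsynonymous_snv	NM_001164317:exon19:c.G2773T:p.G925C	6.33	1.0	0.0	1.0	0	35
chr3	58110119	rs111330368	G	C	40	0.41	0.23	FLNB	nonsynonymous_snv	NM_001164317:exon22:c.G3785C:p.G1262A	6.18	1.0	0.0	1.0	0	35
chr11	6190710	rs372373798	C	T	19	0.01	NA	OR52B2	nonsynonymous_snv	NM_001004052:exon1:c.G847A:p.V283M	2.69	1.0	0.08	1.0	0	35
chr11	6190828	rs190537696	A	T	19	0.1	0.14	OR52B2	stopgain	NM_001004052:exon1:c.T729A:p.C243X	0.59	1.0	1.0	NA	0	35
chr11	92086828	rs139595720	T	C	7	0.66	0.46	FAT3	nonsynonymous_snv	NM_001008781:exon1:c.T1550C:p.L517S	3.32	0.82	0.72	1.0	0	35
chr11	92624235	rs187159256	C	T	7	0.17	0.14	FAT3	nonsynonymous_snv	NM_001008781:exon25:c.C13630T:p.L4544F	0.94	0.96	0.03	0.37	0	35
chr12	49418717	rs201481646	C	T	12	0.07	NA	KMT2D	nonsynonymous_snv	NM_003482:exon49:c.G15797A:p.R5266H	2.39	1.0	0.0	1.0	0	35
chr12	49432365	rs199547661	G	A	12	0.24	0.09	KMT2D	nonsynonymous_snv	NM_003482:exon34:c.C8774T:p.A2925V	0.77	0.38	0.0	0.0	0	35
chr13	109613971	rs374252281	G	A	28	0.01	NA	MYO16	nonsynonymous_snv	NM_001198950:exon18:c.G2122A:p.A708T	4.62	1.0	0.01	1.0	0	35
chr13	109617108	.	G	A	28	NA	NA	MYO16	splice	NM_001198950:exon20:splice acceptor lost	4.87	1.0	NA	NA	0	35
chr14	58924684	rs61742715	T	A	19	0.39	0.23	KIAA0586	nonsynonymous_snv	NM_001244189:exon13:c.T1729A:p.L577I	0.28	0.81	0.43	1.0	0	35
chr14	59014632	rs61745066	G	A	19	0.24	0.18	KIAA0586	nonsynonymous_snv	NM_001244189:exon34:c.G4873A:p.G1625R	-1.15	0.41	0.0	0.0	0	35
chr15	42977116	rs79165890	T	C	12	0.22	0.05	STARD9	nonsynonymous_snv	NM_020759:exon23:c.T3340C:p.C1114R	1.98	0.51	0.0	0.05	0	35
chr15	42977810	rs140924205	T	G	19	0.4	0.32	STARD9	nonsynonymous_snv	NM_020759:exon23:c.T4034G:p.I1345S	0.269	0.001	0.0	0.27	0	35
chr15	42978141	rs376229251	A	C	19	0.09	NA	STARD9	nonsynonymous_snv	NM_020759:exon23:c.A4365C:p.E1455D	0.553	0.067	0.0	0.99	0	35
chr15	42981101	rs202017657	C	G	12,19	0.15	NA	STARD9	nonsynonymous_snv	NM_020759:exon23:c.C7325G:p.P2442R	0.28	0.01	0.0	0.99	0	35
chr15	42982237	rs201340789	G	C	12,19	0.19	NA	STARD9	nonsynonymous_snv	NM_020759:exon23:c.G8461C:p.V2821L	0.28	0.01	0.0	0.99	0	35
chr16	23635348	rs45478192	A	C	13	0.17	0.09	PALB2	nonsynonymous_snv	NM_024675:exon8:c.T2816G:p.L939W	2.83	1.0	0.0	1.0	0	35
chr16	23641275	rs45543843	T	A	13	0.01	NA	PALB2	nonsynonymous_snv	NM_024675:exon5:c.A2200T:p.T734S	2.9	0.97	0.11	1.0	0	35
chr17	34861135	rs200572125	C	T	25	0.03	NA	MYO19	splice	NM_001163735:splice donor lost, exon20	4.98	1.0	NA	NA	0	35
chr17	34871802	rs187710120	T	C	25	0.19	0.05	MYO19	nonsynonymous_snv	NM_001163735:exon8:c.A446G:p.Y149C	4.52	1.0	0.0	1.0	0	35
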