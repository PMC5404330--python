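chrom	pos	rsid	ref	alt	carriers	freq_evs_pct	freq_kg_pct	gene	func_class	coding_change	phylop	phastcons	sift	polyphen	segdup	min_depth
chr1	158532597	rs142215019	G	T	34	0.22	0.1	OR6P1	stopgain	NM_001160325:exon1:c.C798A:p.Y266X	-0.62	0.0	1.0	NA	0	35
chr3	63466576	rs376661036	C	A	30	0.01	NA	SYNPR	stopgain	NM_144642:exon2:c.C93A:p.C31X	-0.72	0.6	1.0	NA	0	35
chr8	39847306	rs199869245	C	T	11	0.05	NA	IDO2	stopgain	NM_194294:exon8:c.C655T:p.R219X	1.9	0.95	1.0	NA	0	35
chr8	107738486	rs145739822	G	A	29	NA	0.14	OXR1	stopgain	NM_001198534:exon1:c.G15A:p.W5X	4.24	1.0	1.0	NA	0	35
chr11	1027390	rs200217410	G	T	8	0.06	NA	MUC6	stopgain	NM_005961:exon17:c.C2109A:p.C703X	0.4	1.0	1.0	NA	0	35
chr11	6190828	rs190537696	A	T	19	0.1	0.14	OR52B2	stopgain	NM_001004052:exon1:c.T729A:p.C243X	0.59	1.0	1.0	NA	0	35
chr16	4745030	rs146701095	C	T	9	0.04	0.05	NUDT16L1	stopgain	NM_001193452:exon3:c.C556T:p.Q186X	1.77	1.0	1.0	NA	0	35
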