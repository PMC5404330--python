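chrom	pos	ref	alt	stop_aa_pos	protein_length
chr1	158532597	G	T	266	317
chr3	63466576	C	A	31	196
chr8	39847306	C	T	219	432
chr8	107738486	G	A	5	174
chr11	1027390	G	T	703	2439
chr11	6190828	A	T	243	323
chr16	4745030	C	T	186	192
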