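pos	ref	alt	wp_index	mp_index	region	orf	mutation_type
26201284	T	A	0.48	1	Intronic	ORF1	S
26056055	C	T	0.35	1	Exonic	ORF2	NS
25512848	C	T	0.35	1	Intronic	ORF3	S
24400012	G	A	1	1	Intronic	ORF4	S
23899324	C	T	0.1	1	Intergenic		S
23818910	C	T	1	1	Downstream	ORF5	S
18279215	A	C	1	1	Intergenic		S
17267695	C	G	1	1	Exonic	ORF6	NS
4148836	G	T	1	1	Intergenic		S
1935199	C	A	1	1	Intronic	ORF7	S
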