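chrom	pos	rsid	ref	alt	gene	func_class
chr1	3389970	.	G	A	ARHGEF16	missense
chr2	74763923	.	G	GC	LOXL3	frameshift
chr6	151815279	rs199768731	A	C	CCDC170	missense
chr6	157528243	.	C	T	ARID1B	missense
chr7	22184668	.	G	A	RAPGEF5	missense
chr11	89883678	.	G	A	NAALAD2	missense
chr15	75982085	rs79463888	C	T	CSPG4	missense
chr16	3025782	.	G	A	PKMYT1	missense
chr16	30750387	.	G	A	SRCAP	missense
chr16	85682289	.	A	AC	KIAA0182	frameshift
chr17	7577121	rs121913343	G	A	TP53	missense
chr17	77111776	.	C	G	RBFOX3	missense
chr19	6374295	.	G	A	ALKBH7	missense
chr19	54649413	.	G	A	CNOT3	missense
chr20	60775922	rs35693261	C	T	GTPBP5	missense
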