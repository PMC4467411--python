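chrom	pos	rsid	ref	alt	gene	func_class
chr1	1334519	rs114112990	G	C	CCNL2	missense
chr1	1354515	rs904589	C	G	ANKRD65	missense
chr1	19181015	rs34447754	G	C	TAS1R2	missense
chr1	20977000	rs1043424	A	C	PINK1	missense
chr1	168013850	rs11558511	T	C	DCAF6	missense
chr1	169498975	rs6030	T	C	F5	missense
chr1	169511555	rs6032	T	C	F5	missense
chr1	169511734	rs4525	T	C	F5	missense
chr1	169511755	rs4524	T	C	F5	missense
chr1	175092707	rs10798333	C	T	TNN	missense
chr1	196642233	rs800292	G	A	CFH	missense
chr1	200635550	rs3795634	T	C	DDX59	missense
chr1	201166383	rs4915221	G	A	IGFN1	missense
chr1	203152801	rs880633	T	C	CHI3L1	missense
chr1	207753621	rs2274567	A	G	CR1	missense
chr1	207782931	rs6691117	A	G	CR1	missense
chr1	207790088	rs3811381	C	G	CR1	missense
chr1	247615261	.	GA	G	OR2B11	frameshift
chr1	248020556	rs11204523	G	C	TRIM58	missense
chr2	10262920	rs1130609	T	G	RRM2	missense
chr2	71212129	rs3796100	A	T	ANKRD53	missense
chr2	71212405	rs61732279	T	C	ANKRD53	missense
chr2	85622059	rs6886	T	C	CAPG	missense
chr2	86400824	rs1050301	G	A	IMMT	missense
chr2	88472791	rs4129190	G	A	THNSL2	missense
chr2	209190632	rs999890	T	G	PIKFYVE	missense
chr2	228102723	rs13424243	G	C	COL4A3	missense
chr3	4508742	rs2819590	C	T	SUMF1	missense
chr5	122718736	rs6595440	G	C	CEP120	missense
chr5	141059158	rs1031904	C	G	ARAP3	missense
chr5	149001551	rs4629585	A	C	ARHGEF37	missense
chr5	149772280	rs1136103	C	G	TCOF1	missense
chr5	150886882	rs1105168	G	A	FAT2	missense
chr5	180582604	rs2546423	A	G	OR2V2	missense
chr6	12124587	rs2228212	C	G	HIVEP1	missense
chr7	6026988	rs1805321	G	A	PMS2	missense
chr7	87564497	rs2279542	C	G	ADAM22	missense
chr7	88424115	rs2373396	C	G	C7orf62	missense
chr8	72975801	rs7819749	T	G	TRPA1	missense
chr8	133975283	rs2069561	G	A	TG	missense
chr11	3681519	rs2280134	T	C	ART1	missense
chr11	5718517	rs7935564	G	A	TRIM22	missense
chr11	18743180	rs10832975	C	G	IGSF22	missense
chr11	60776209	rs11230563	C	T	CD6	missense
chr11	60893235	rs2229177	C	T	CD5	missense
chr11	62863518	rs7113279	A	G	SLC22A24	missense
chr11	66083129	rs3741367	T	C	CD248	missense
chr11	69063393	rs7103126	T	C	MYEOV	missense
chr11	93457532	rs78544176	C	G	KIAA1731	missense
chr12	18435452	rs11044004	C	T	PIK3C2G	missense
chr12	25243115	rs1908946	G	C	LRMP	missense
chr12	29604392	rs1347570	C	G	OVCH1	missense
chr14	21500121	rs9624	G	T	TPPP2	missense
chr14	21796784	rs3748361	G	C	RPGRIP1	missense
chr14	76156609	rs2303345	C	T	TTLL5	missense
chr14	88651962	rs17762463	C	T	KCNK10	missense
chr14	91636532	rs4900072	C	T	C14orf159	missense
chr15	78466127	rs2304824	T	C	ACSBG1	missense
chr15	89398407	rs3743398	C	T	ACAN	missense
chr15	90126121	rs10775247	C	T	C15orf42	missense
chr15	90128966	rs11629584	C	T	C15orf42	missense
chr15	90174824	rs12900805	C	T	KIF7	missense
chr15	90176073	rs3803530	C	A	KIF7	missense
chr16	71483497	rs72795864	C	G	ZNF23	missense
chr16	88504850	rs1105066	G	C	ZNF469	missense
chr16	89350038	rs2279348	G	A	ANKRD11	missense
chr17	37814080	rs1877031	G	A	STARD3	missense
chr17	37879588	rs1136201	A	G	ERBB2	missense
chr17	37884037	rs61552325	C	G	ERBB2	missense
chr17	55182878	rs17761023	C	T	AKAP1	missense
chr17	55183792	rs35359994	G	A	AKAP1	missense
chr17	55183813	rs34535433	A	G	AKAP1	missense
chr17	66538239	rs2302234	G	T	FAM20A	missense
chr17	67125840	rs4968839	C	T	ABCA6	missense
chr17	67178316	rs4968849	A	G	ABCA10	missense
chr17	67212423	rs9909216	G	A	ABCA10	missense
chr17	76528790	rs11651537	A	G	DNAH17	missense
chr18	6997818	rs12961939	A	C	LAMA1	missense
chr21	37617630	rs4817788	T	G	DOPEY2	missense
chr22	26222454	rs9624909	C	T	MYO18B	missense
chr22	29885016	rs59371099	G	A	NEFH	missense
chr22	30762140	rs740223	G	A	CCDC157	missense
chr22	30776095	rs5749088	C	T	RNF215	missense
chr22	31491295	rs3205187	G	C	SMTN	missense
chr22	36537763	rs61741884	C	T	APOL3	missense
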