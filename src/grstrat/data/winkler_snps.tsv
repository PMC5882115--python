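rsid	locus	effect_allele	weight
rs2476601	PTPN22	A	0.246
rs3087243	CTLA4	T	0.229
rs2292239	ERBB3	G	0.244
rs12708716	CLEC16A	A	0.072
rs2542151	PTPN2	T	0.226
rs7804356	SKAP2	A	0.072
rs12722495	IL2RA	A	0.427
rs3184504	SH2B3	G	0.182
rs10509540	RNLS	T	0.401
rs4948088	COBL	C	0.092
rs7202877	CTRB1	C	0.287
rs2281808	SIRPG	T	0.389
rs11594656	IL2RA	T	0.295
rs4788084	IL27	T	0.069
rs5753037	HORMAD2	A	0.354
rs10517086	AC080079	G	0.122
rs1465788	ZFP36L1	A	0.309
rs2290400	GSDMB	T	0.152
rs11755527	BACH2	G	0.239
rs689	INS	G	0.243
rs2069763	IL2	A	-0.1
rs3825932	CTSH	G	-0.08
rs917997	IL18RAP	T	0.424
rs2816316	RGS1	C	0.339
rs11711054	CCR5	C	0.382
rs10499194	TNFAIP3	T	0.434
rs6920220	TNFAIP3	C	0.074
rs7020673	GLIS3	G	0.374
rs12251307	IL2RA	G	0.321
rs4763879	CD69	T	0.166
rs1678536	CD226	G	0.238
rs3024505	IL10	T	0.073
rs9653442	AFF3	G	0.148
rs11580078	RGS1	C	0.148
rs6691977	TRAF3IP2	C	0.269
rs2611215	CPE	C	0.377
rs11954020	IL7R	T	0.065
rs924043	WDR27	G	0.115
rs7738609	VEGFA	G	0.303
rs1738074	TAGAP	G	0.113
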