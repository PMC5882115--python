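rsid	locus	effect_allele	weight
rs2476601	PTPN22	A	0.32
rs3087243	CTLA4	T	0.205
rs2292239	ERBB3	G	0.384
rs12708716	CLEC16A	A	0.192
rs2542151	PTPN2	T	0.368
rs7804356	SKAP2	A	0.339
rs12722495	IL2RA	A	0.345
rs3184504	SH2B3	G	0.306
rs10509540	RNLS	T	0.153
rs4948088	COBL	C	0.323
rs7202877	CTRB1	C	0.333
rs2281808	SIRPG	T	0.061
rs11594656	IL2RA	T	0.144
rs4788084	IL27	T	0.335
rs5753037	HORMAD2	A	0.303
rs10517086	AC080079	G	0.09
rs1465788	ZFP36L1	A	0.283
rs2290400	GSDMB	T	0.333
rs11755527	BACH2	G	0.168
rs689	INS	G	0.236
rs2069763	IL2	A	0.2
rs3825932	CTSH	G	0.15
rs2395029	HCP5	C	0.309
rs41295061	IL2RA	A	0.316
rs9268645	HLA-DRA	T	0.318
rs3129889	HLA-DRA	T	0.18
rs1264813	HLA-A	G	0.287
rs2187668	HLA-DQA1	G	0.379
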