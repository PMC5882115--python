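rsid	maf
rs1004446	0.11
rs10499194	0.396
rs10509540	0.408
rs10517086	0.436
rs11580078	0.323
rs11594656	0.427
rs11711054	0.215
rs11954020	0.387
rs12251307	0.472
rs12708716	0.42
rs12722495	0.321
rs1465788	0.375
rs1678536	0.253
rs1738074	0.135
rs2069763	0.142
rs2281808	0.356
rs2290400	0.106
rs2292239	0.328
rs2395029	0.252
rs2476601	0.294
rs2542151	0.475
rs2611215	0.133
rs2816316	0.418
rs3024505	0.248
rs3087243	0.377
rs3129889	0.197
rs3184504	0.425
rs3757247	0.301
rs3825932	0.303
rs41295061	0.423
rs4763879	0.301
rs4788084	0.361
rs4948088	0.358
rs5753037	0.166
rs6691977	0.388
rs6920220	0.314
rs7020673	0.249
rs7202877	0.395
rs7738609	0.421
rs7804356	0.169
rs924043	0.317
rs9268645	0.411
rs9653442	0.475
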