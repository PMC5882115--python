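genotype_class	weight
DR3/DR4-DQ8	7.2
DR4-DQ8/DR4-DQ8	6.8
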