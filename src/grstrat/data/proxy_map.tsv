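missing_rsid	proxy_rsid
rs11755527	rs3757247
rs689	rs1004446
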