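dataset,matches,region_bp
genome,4300,12100000
oridb_origins,875,1900000
gemsa_0.3nM,1038,1800000
gemsa_3nM,1062,1800000
gemsa_30nM,1149,1900000
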