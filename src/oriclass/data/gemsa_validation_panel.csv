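origin,orc21_orc2_ratio,kd_nM,kd_stderr_nM,acs_status,newly_tested,emsa_prior_class
ARS1015,0.81,63.13,4.3,confirmed,1,
ARS815,0.81,,,unconfirmed,0,
ARS1114,0.82,33.29,2.4,confirmed,1,
ARS1307,0.82,83.7,3.0,confirmed,1,
ARS305,0.83,33.07,2.3,confirmed,1,
ARS1513,0.83,56.30,4.7,confirmed,1,
ARS428,0.83,91.6,4.2,confirmed,1,
ARS447,0.84,,,unconfirmed,0,
ARS1116,0.84,,,unconfirmed,0,
ARS609,0.86,,,unconfirmed,0,
ARS1332,0.88,35.29,0.88,confirmed,0,complex
ARS516,0.88,27.76,1.4,confirmed,0,dna_dependent
ARS105,0.88,ND,,confirmed,0,chromatin_dependent
ARS1521,0.94,90.13,2.36,confirmed,0,chromatin_dependent
ARS1528,0.95,ND,,confirmed,0,chromatin_dependent
ARS1529.5,0.98,191.6,18.98,confirmed,0,chromatin_dependent
ARS1005,1.03,ND,,confirmed,1,
ARS1016,1.05,,,unconfirmed,0,
ARS1618.5,1.11,,,unconfirmed,0,
ARS219.5,1.27,ND,,confirmed,0,chromatin_dependent
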