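origin,orc21_orc2_ratio,kd_nM,kd_stderr_nM,acs_status,panel
ARS728,-0.112,8.38,1.11,confirmed,low
ARS1325,-0.079,63.04,1.943,confirmed,low
ARS911,-0.046,87.33,2.205,confirmed,low
ARS1329,0.004,76.8,4.002,confirmed,low
ARS1631,0.018,26.79,1.192,confirmed,low
ARS512,0.022,55.06,1.556,confirmed,low
ARS1413,0.022,418.9,21.76,confirmed,low
ARS920,0.057,8.652,1.116,confirmed,low
ARS604,0.072,61.03,2.888,confirmed,low
ARS1405,0.09,97.18,4.689,confirmed,low
ARS1004,0.114,92.27,2.121,confirmed,low
ARS1323,0.139,58.62,3.024,confirmed,low
ARS818,0.161,93.96,4.237,confirmed,low
ARS716,0.169,39.21,5.439,confirmed,low
ARS214,0.198,41.33,1.409,confirmed,low
ARS822,0.201,260.3,13.74,confirmed,low
ARS809,0.216,ND,,confirmed,low
ARS1215,0.229,55.8,2.055,predicted,none
ARS720,0.242,33.9,2.715,confirmed,low
ARS416,0.551,35.07,1.223,confirmed,moderate
ARS824,0.871,38.11,2.034,predicted,high
ARS423,0.872,6.757,1.214,confirmed,high
ARS1332,0.876,35.29,0.8786,confirmed,high
ARS516,0.878,27.76,1.439,confirmed,high
ARS105,0.885,ND,,confirmed,high
ARS1625,0.889,8.669,1.295,confirmed,high
ARS201,0.903,20.13,1.65,predicted,high
ARS1601,0.916,32.75,1.287,predicted,high
ARS1521,0.94,90.13,2.361,confirmed,high
ARS1528,0.947,ND,,confirmed,high
ARS1123,0.948,12.35,1.231,confirmed,high
ARS1529.5,0.98,191.6,18.98,confirmed,high
ARS1011,0.982,11.07,0.8141,confirmed,high
ARS1021,1.003,17.9,0.8416,confirmed,high
ARS1420,1.003,17.82,1.48,confirmed,high
ARS422,1.003,9.853,1.168,confirmed,high
ARS317,1.014,7.223,0.6519,confirmed,high
ARS514,1.06,4.116,0.7319,confirmed,high
ARS1320,1.067,20.95,1.617,confirmed,high
ARS219.5,1.273,ND,,confirmed,high
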