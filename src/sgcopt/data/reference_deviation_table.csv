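amino_acid,BLAM930101,BIOV880101,MAXF760101,TSAJ990101,NAKH920108,CEDJ970104,LIFS790101,MIYS990104,average,codons_best_us,codons_sgc
Ala,0.516,0.043,0.243,0.239,0.262,0.337,0.062,0.067,0.221,2,4
Arg,0.318,0.498,0.093,0.207,0.284,0.012,0.057,0.400,0.234,1,6
Asn,0.078,0.519,0.230,0.093,0.162,0.116,0.239,0.582,0.252,3,2
Asp,0.047,0.540,0.062,0.128,0.244,0.058,0.305,0.764,0.269,5,2
Cys,0.047,0.762,0.050,0.181,0.147,0.360,0.070,0.964,0.323,1,2
Gln,0.349,0.513,0.117,0.015,0.232,0.070,0.046,0.612,0.244,1,2
Glu,0.068,0.688,0.387,0.020,0.244,0.244,0.233,0.885,0.346,1,2
Gly,0.484,0.196,0.338,0.352,0.070,0.244,0.233,0.461,0.297,4,4
His,0.109,0.137,0.026,0.062,0.272,0.337,0.057,0.067,0.133,2,2
Ile,0.391,0.672,0.010,0.087,0.525,0.023,0.430,0.842,0.372,1,3
Leu,0.474,0.640,0.201,0.087,0.700,0.419,0.148,0.933,0.450,1,6
Lys,0.276,0.873,0.147,0.096,0.266,0.198,0.184,1.188,0.403,1,2
Met,0.411,0.529,0.303,0.099,0.064,0.302,0.087,0.721,0.315,1,1
Phe,0.130,0.873,0.099,0.209,0.360,0.128,0.120,0.964,0.360,1,2
Pro,3.089,0.233,0.320,0.096,0.183,0.035,0.349,0.764,0.634,1,4
Ser,0.068,0.498,0.194,0.217,0.035,0.186,0.117,0.552,0.233,16,6
Thr,0.078,0.328,0.146,0.105,0.019,0.035,0.048,0.279,0.130,16,4
Trp,0.120,0.640,0.008,0.367,0.168,0.442,0.280,0.812,0.355,1,1
Tyr,0.266,0.153,0.200,0.226,0.112,0.221,0.275,0.691,0.268,1,2
Val,0.172,0.524,0.026,0.023,0.445,0.209,0.424,0.691,0.314,1,4
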