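X,Y,V,dV,r_x,dr_x,r_y,dr_y
AS,ASL,0.01409,0.00278,7.89602,1.15697,0.02587,0.00831
AS,ASpOH,0.18894,0.00602,21.98121,0.77727,1.1015,0.28638
AS,ASoOH,0.14413,0.00551,11.83904,1.2386,0.0113,0.00335
AS,ASLpOH,0.22182,0.00787,21.49879,0.83576,0.00581,0.00195
AS,ASLoOH,0.15519,0.00648,14.8091,1.21547,0.00115,0.00051
ASL,ASpOH,0.02149,0.00371,0.06383,0.01181,1.68862,0.33941
ASL,ASoOH,0.0088,0.0023,0.03706,0.00968,0.0141,0.00337
ASL,ASLpOH,0.02205,0.00359,0.06781,0.01255,0.01302,0.00277
ASL,ASLoOH,0.02136,0.00357,0.0314,0.00899,0.0044,0.00093
ASpOH,ASoOH,0.08236,0.00556,0.67428,0.22974,0.03678,0.0048
ASpOH,ASLpOH,0.16705,0.0088,2.02965,0.363,0.02244,0.00335
ASpOH,ASLoOH,0.10716,0.00735,1.18772,0.29582,0.00697,0.00102
ASoOH,ASLpOH,0.09526,0.00632,0.03102,0.00477,0.0053,0.00186
ASoOH,ASLoOH,0.06552,0.0056,0.01263,0.0031,0.00073,0.0004
ASLpOH,ASLoOH,0.12782,0.00696,0.00592,0.00197,0.00504,0.00096
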