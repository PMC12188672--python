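X,Y,V,dV,r_x,dr_x,r_y,dr_y
AS,ASL,0.0711,0.00315,20.21159,2.24584,0.00818,0.00442
AS,ASpOH,0.01572,0.00243,35.4932,1.83947,0.71494,0.35179
AS,ASoOH,0,0,29.65423,2.13934,0.46465,0.20335
AS,ASLpOH,0,0,28.78377,2.16983,0.02958,0.01066
AS,ASLoOH,0.00734,0.00169,22.00105,2.25597,0.01685,0.00652
ASL,ASpOH,0.00933,0.00179,0.14796,0.01289,3.21513,0.68965
ASL,ASoOH,0.00905,0.00175,0.12975,0.013,2.3137,0.40277
ASL,ASLpOH,0.00867,0.00173,0.06732,0.01135,0.1295,0.0194
ASL,ASLoOH,0.00399,0.00148,0.10725,0.01287,0.04891,0.01044
ASpOH,ASoOH,0.05968,0.00501,5.19208,0.81646,5.27732,0.46076
ASpOH,ASLpOH,0.07513,0.00643,3.75687,0.73229,0.23814,0.02078
ASpOH,ASLoOH,0.09565,0.00729,3.39563,0.70461,0.09287,0.01298
ASoOH,ASLpOH,0.10544,0.00627,2.50242,0.41355,0.17977,0.02078
ASoOH,ASLoOH,0.10869,0.00735,2.21348,0.39589,0.08816,0.01289
ASLpOH,ASLoOH,0.10818,0.00746,0.15052,0.02014,0.07067,0.01193
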