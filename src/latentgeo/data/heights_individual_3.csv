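X,Y,h,dh,flag
AS,ASL,0.000215,6.3e-05,
AS,ASpOH,0.000355,2.5e-05,
AS,ASoOH,0.000981,0.000205,
AS,ASLpOH,0.000458,3.6e-05,
AS,ASLoOH,0.000676,0.000111,
ASL,ASpOH,0.006925,0.00276,
ASL,ASoOH,4.011544,500.514571,high_se
ASL,ASLpOH,3.726363,107.375536,high_se
ASL,ASLoOH,17.837914,2607.265753,high_se
ASpOH,ASoOH,0.163575,0.110694,
ASpOH,ASLpOH,0.038296,0.01363,
ASpOH,ASLoOH,0.072114,0.035985,
ASoOH,ASLpOH,78.776939,4526.141571,high_se
ASoOH,ASLoOH,369.629008,186638.464989,high_se
ASLpOH,ASLoOH,1351.934201,815363.824841,high_se
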