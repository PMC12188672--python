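X,Y,h,dh,flag
AS,ASL,0.000166,3.7e-05,
AS,ASpOH,1.2e-05,1e-06,
AS,ASoOH,0,0,no_interaction
AS,ASLpOH,0,0,no_interaction
AS,ASLoOH,1.4e-05,3e-06,
ASL,ASpOH,0.000822,0.000345,
ASL,ASoOH,0.001524,0.000518,
ASL,ASLpOH,0.275789,1.83425,high_se
ASL,ASLoOH,0.199065,3.85797,high_se
ASpOH,ASoOH,0.000693,0.000124,
ASpOH,ASLpOH,0.004762,0.001795,
ASpOH,ASLoOH,0.007705,0.003153,
ASoOH,ASLpOH,0.014929,0.00475,
ASoOH,ASLoOH,0.020342,0.007132,
ASLpOH,ASLoOH,2.698102,4.89419,high_se
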