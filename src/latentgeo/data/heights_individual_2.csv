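X,Y,h,dh,flag
AS,ASL,0.000406,7.5e-05,
AS,ASpOH,0.000706,0.000196,
AS,ASoOH,0.000145,7e-06,inconsistent_with_cone_table
AS,ASLpOH,0.0004,0.000151,
AS,ASLoOH,0.000371,8.2e-05,
ASL,ASpOH,0.561439,1.171119,high_se
ASL,ASoOH,6.604244,23.674886,high_se
ASL,ASLpOH,0,0,no_interaction
ASL,ASLoOH,1.839596,23.258452,high_se
ASpOH,ASoOH,0.030531,0.006734,
ASpOH,ASLpOH,0.044446,0.012959,
ASpOH,ASLoOH,0.012699,0.002959,
ASoOH,ASLpOH,0,0,no_interaction
ASoOH,ASLoOH,0.066804,0.020935,
ASLpOH,ASLoOH,2043.937613,9729268.669899,high_se
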