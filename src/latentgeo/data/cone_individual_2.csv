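X,Y,V,dV,r_x,dr_x,r_y,dr_y
AS,ASL,0.09853,0.00557,15.22469,1.4123,0.00549,0.00368
AS,ASpOH,0.06892,0.00525,9.59555,1.34368,0.12032,0.06931
AS,ASoOH,0.10948,0.00622,6.78193,0.61782,0.22568,0.08268
AS,ASLpOH,0.01616,0.00203,6.21433,1.17603,0.00063,0.00025
AS,ASLoOH,0.06254,0.00429,12.68739,1.40977,6e-05,2e-05
ASL,ASpOH,0.04025,0.00545,0.06607,0.01144,0.22228,0.08849
ASL,ASoOH,0.11982,0.00743,0.13152,0.01322,0.00021,3e-05
ASL,ASLpOH,0,0,0.07147,0.01174,0.0002,0.00011
ASL,ASLoOH,0.02352,0.00363,0.1104,0.013,0.00019,4e-05
ASpOH,ASoOH,0.1139,0.00702,1.52475,0.19422,0.58625,0.1257
ASpOH,ASLpOH,0.07603,0.00471,1.2768,0.18474,0.00257,0.00045
ASpOH,ASLoOH,0.03939,0.00455,1.72077,0.19769,0.00059,6e-05
ASoOH,ASLpOH,0,0,0.77777,0.13902,0.00381,0.00052
ASoOH,ASLoOH,0.06612,0.00397,0.9719,0.14917,0.00058,7e-05
ASLpOH,ASLoOH,0.04891,0.00532,0.00444,0.00055,0.00062,7e-05
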