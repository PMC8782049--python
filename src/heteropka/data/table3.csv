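compound,delta_e,exp_pka1,calc_pka1,residual
azauracil,-1084,-,<<0,-
aziridine,-1216,8.01,7.76,0.25
creatinine,-1188,4.8,4.09,0.71
cytosine,-1183,4.5,3.43,1.07
flucytosine,-1169,3.26,1.60,1.66
imidazole,-1213,7.07,7.36,-0.29
1-methylimidazole,-1216,7.95,7.76,0.19
4-methylimidazole,-1215,7.55,7.63,-0.08
isocytosine,-1183,4.01,3.43,0.58
isoxazole,-1115,-2,<0,-
maleimide,-1035,-,<<0,-
oxazole,-872,0.8,<<0,-
piperidine,-1239,11.12,10.77,0.35
piperazine,-1226,9.76,9.07,0.69
1-methylpiperazine,-1231,10.19,9.72,0.47
pyrazine,-1166,0.65,1.21,-0.56
pyrazole,-1174,2.61,2.25,0.36
pyridazine,-1186,2.3,3.83,-1.53
pyridine,-1200,5.23,5.66,-0.43
pyrimidine,-1172,1.3,1.99,-0.69
pyrrolidine,-1239,11.71,10.77,0.94
succinimide,-1007,-,<<0,-
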