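compound,delta_e,exp_pka2,calc_pka2,residual
azauracil,-1179,-,6.82,-
aziridine,-1325,-,27.41,-
creatinine,-1217,-,12.18,-
cytosine,-1216,12.57,12.04,0.53
isocytosine,-1196,9.42,9.22,0.20
flucytosine,-1254,-,17.39,-
imidazole,-1216,14.4,12.04,2.36
4-methylimidazole,-1224,-,13.16,-
maleimide,-1196,9.5,9.22,0.28
piperazine,-1313,-,25.71,-
1-methylpiperazine,-1395,-,37.28,-
piperidine,-1310,-,25.29,-
pyrrole,-1243,17,15.84,1.16
pyrrolidine,-1390,-,36.57,-
thymine,-1199,9.71,9.64,0.07
uracil,-1200,9.44,9.78,-0.34
5-bromouracil,-1184,7.91,7.52,0.39
5-chlorouracil,-1182,7.92,7.24,0.68
fluorouracil,-1193,7.99,8.79,-0.80
5-formyluracil,-1180,6.84,6.96,-0.12
5-nitrouracil,-1159,5.3,4.00,1.30
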